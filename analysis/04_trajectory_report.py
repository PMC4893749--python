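"""Summarise community trajectories from the pipeline run.

Reads the Bray-Curtis distance-to-baseline table and the PERMANOVA
screen written by 03_run_pipeline and reports, per group and day, how
far each community has moved from its own day -1 state — the check that
the invader group's shift runs ahead of the plain DSS group's.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "pipeline"
OUT = ROOT / "results"


def main() -> None:
    baseline_path = RUN / "distance_to_baseline.tsv"
    if not baseline_path.exists():
        raise SystemExit("run analysis/03_run_pipeline.py first")
    baseline = pd.read_csv(baseline_path, sep="\t", index_col="sample_id")
    traj = (
        baseline.groupby(["group", "day"])["distance_to_baseline"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    traj.to_csv(OUT / "trajectories.tsv", sep="\t", index=False)
    print("mean Bray-Curtis distance to own day -1 baseline:")
    print(traj.pivot(index="day", columns="group", values="mean").round(3))

    wide = traj.pivot(index="day", columns="group", values="mean")
    if {"DSS", "DSS+BPB5"} <= set(wide.columns):
        d4 = wide.loc[4]
        lead = d4["DSS+BPB5"] - d4["DSS"]
        print(
            f"\nday 4: invader group is {lead:+.3f} further from baseline "
            f"than DSS ({d4['DSS+BPB5']:.3f} vs {d4['DSS']:.3f})"
            + (" -> accelerated shift" if lead > 0 else "")
        )
    screen = pd.read_csv(RUN / "permanova_screen.tsv", sep="\t")
    print("\nPERMANOVA screen (9999 permutations):")
    print(
        screen[["contrast", "pseudo_F", "p_value", "significant"]]
        .round({"pseudo_F": 2, "p_value": 4})
        .to_string(index=False)
    )
    print(f"\nwrote trajectories.tsv -> {OUT}")


if __name__ == "__main__":
    main()
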