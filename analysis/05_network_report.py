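"""Summarise the SparCC network, CAG structure and invader correlates.

Reads the artifacts of 03_run_pipeline and reports CAG sizes, the days
at which each CAG first differs from the DSS reference in each group,
and the taxa correlated with the invader beyond |rho| > 0.5 — the
network-level view of how the invader reorganises the community.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "pipeline"
OUT = ROOT / "results"


def main() -> None:
    if not (RUN / "summary.json").exists():
        raise SystemExit("run analysis/03_run_pipeline.py first")
    summary = json.loads((RUN / "summary.json").read_text())
    assignment = pd.read_csv(RUN / "cag_assignment.tsv", sep="\t")
    dynamics = pd.read_csv(RUN / "cag_dynamics.tsv", sep="\t")
    edges = pd.read_csv(RUN / "network_edges.tsv", sep="\t")

    sizes = assignment.groupby("cag")["otu"].count()
    print(f"{summary['n_key_otus']} key OTUs in {summary['n_cags']} CAGs:")
    for cag, n in sizes.items():
        print(f"  {cag}: {n} OTUs")
    print(
        f"network: {len(edges)} edges with |rho| > 0.5 "
        f"({(edges['sign'] == 'positive').sum()} positive, "
        f"{(edges['sign'] == 'negative').sum()} negative)"
    )

    sig = dynamics[dynamics["adjusted_p"] < 0.05]
    first_sig = (
        sig[sig["day"] >= 0]
        .groupby(["cag", "group"])["day"]
        .min()
        .unstack()
    )
    first_sig.to_csv(OUT / "cag_first_divergence.tsv", sep="\t")
    print("\nfirst day each CAG differs from the DSS reference (FDR < 0.05):")
    print(first_sig)

    pos = summary.get("invader_positive_correlates", [])
    neg = summary.get("invader_negative_correlates", [])
    print(f"\ninvader correlates: {len(pos)} positive {pos}, {len(neg)} negative {neg}")
    print(f"wrote cag_first_divergence.tsv -> {OUT}")


if __name__ == "__main__":
    main()
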