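"""End-to-end orchestration: config, staged execution, artifacts, summary.

Stages run in a fixed order (input -> rarefy -> diversity -> ordination
-> PERMANOVA screen -> key OTUs -> SparCC -> CAGs -> dynamics ->
differential tables), each writing plain-text artifacts into the run
directory. Every stochastic stage carries an explicit seed in the
config; a run log records every parameter actually used, and a
machine-readable summary.json collects the headline quantities.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import cag as cagmod
from . import diversity, keyotu, permanova, simulate, sparcc
from .containers import OtuTable
from .stats import differential_otus, results_to_frame

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputConfig(_Strict):
    counts_tsv: str | None = None
    metadata_tsv: str | None = None


class SyntheticConfig(_Strict):
    seed: int
    shift_lead_days: int = 3
    effect_log2_fold: float = 4.0
    within_block_corr: float = 0.8


class RarefactionConfig(_Strict):
    seed: int
    depth: int = 9000
    n_rep: int = 1000


class PermanovaConfig(_Strict):
    seed: int
    n_perm: int = 9999
    alpha: float = 0.05


class KeyOtuConfig(_Strict):
    seed: int
    n_trees: int = 1000
    mda_threshold: float = 0.003
    max_class_error: float = 0.0


class SparccConfig(_Strict):
    seed: int
    n_est_iter: int = 20
    exclusion_threshold: float = 0.1
    max_exclusions: int = 10
    n_null: int = 100
    null_est_iter: int = 5
    edge_threshold: float = 0.5


class CagConfig(_Strict):
    seed: int
    alpha: float = 0.005
    n_perm: int = 9999
    reference_group: str = "DSS"


class DifferentialConfig(_Strict):
    alpha_fdr: float = 0.05


class PipelineConfig(_Strict):
    output_dir: str
    input: InputConfig | None = None
    synthetic: SyntheticConfig | None = None
    contrasts: list[list] | None = None  # [[group_a, day_a, group_b, day_b], ...]
    invader_otu: str | None = simulate.INVADER_OTU_ID
    rarefaction: RarefactionConfig
    permanova: PermanovaConfig
    keyotu: KeyOtuConfig
    sparcc: SparccConfig
    cag: CagConfig
    differential: DifferentialConfig = DifferentialConfig()
    resume: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def default_config(output_dir: str, seed: int = 0) -> PipelineConfig:
    """A fully seeded default configuration over the synthetic cohort."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)]
    return PipelineConfig(
        output_dir=output_dir,
        synthetic=SyntheticConfig(seed=seeds[0]),
        rarefaction=RarefactionConfig(seed=seeds[1]),
        permanova=PermanovaConfig(seed=seeds[2]),
        keyotu=KeyOtuConfig(seed=seeds[3]),
        sparcc=SparccConfig(seed=seeds[4]),
        cag=CagConfig(seed=seeds[5]),
    )


def default_contrasts(metadata: pd.DataFrame) -> list[tuple]:
    """Treatment-vs-control and invader-vs-disease cells per post-baseline day.

    Mirrors the study logic: DSS vs PBS gauges the colitis shift,
    DSS+BPB5 vs DSS gauges the invader's added effect.
    """
    days = sorted(d for d in metadata["day"].unique() if d > metadata["day"].min())
    groups = set(metadata["group"].unique())
    pairs = []
    if {"DSS", "PBS"} <= groups:
        pairs.append(("DSS", "PBS"))
    if {"DSS+BPB5", "DSS"} <= groups:
        pairs.append(("DSS+BPB5", "DSS"))
    if not pairs:  # generic fallback: all group pairs
        gs = sorted(groups)
        pairs = [(a, b) for i, a in enumerate(gs) for b in gs[i + 1 :]]
    return [((a, d), (b, d)) for d in days for a, b in pairs]


STAGE_ORDER = (
    "input",
    "rarefy",
    "diversity",
    "ordination",
    "permanova",
    "keyotu",
    "sparcc",
    "cag",
    "differential",
    "summary",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    With ``resume=True`` a stage whose artifacts already exist on disk
    is loaded instead of recomputed, so a run can be restarted per
    stage without changing results. Any stage failure raises a
    stage-named error; artifacts of completed stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("cagflow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config_used.yaml")
        state: dict = {"summary": {}}
        for stage in STAGE_ORDER:
            try:
                logger.info("stage %s starting", stage)
                _STAGES[stage](config, out, state)
                logger.info("stage %s done", stage)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(stage, exc) from exc
        return out
    finally:
        root.removeHandler(handler)
        handler.close()


# ----------------------------------------------------------------- stages


def _stage_input(config: PipelineConfig, out: Path, state: dict) -> None:
    counts_p, meta_p = out / "counts.tsv", out / "metadata.tsv"
    if config.resume and counts_p.exists() and meta_p.exists():
        table = OtuTable.from_tsv(counts_p, meta_p)
    elif config.input is not None and config.input.counts_tsv:
        table = OtuTable.from_tsv(
            config.input.counts_tsv, config.input.metadata_tsv
        )
        table.to_tsv(counts_p, meta_p)
    elif config.synthetic is not None:
        design = simulate.build_default_design()
        effects = simulate.EffectSpec(
            shift_lead_days=config.synthetic.shift_lead_days,
            effect_log2_fold=config.synthetic.effect_log2_fold,
            within_block_corr=config.synthetic.within_block_corr,
        )
        table, truth = simulate.simulate_otu_table(
            design, effects, seed=config.synthetic.seed
        )
        table.to_tsv(counts_p, meta_p)
        truth.block_assignments.to_csv(out / "truth_blocks.tsv", sep="\t")
        state["truth"] = truth
        logger.info(
            "simulated cohort: %d samples x %d OTUs, seed=%d",
            table.n_samples,
            table.n_otus,
            config.synthetic.seed,
        )
    else:
        raise ValueError("config needs either an input table or a synthetic block")
    state["table"] = table


def _stage_rarefy(config: PipelineConfig, out: Path, state: dict) -> None:
    cfg = config.rarefaction
    counts_p, meta_p = out / "rarefied_counts.tsv", out / "rarefied_metadata.tsv"
    if config.resume and counts_p.exists():
        sub = OtuTable.from_tsv(counts_p, meta_p)
        rt = diversity.RarefiedTable(
            table=sub,
            depth=cfg.depth,
            n_repetitions=cfg.n_rep,
            excluded_samples=[
                s for s in state["table"].sample_ids if s not in set(sub.sample_ids)
            ],
            seed=cfg.seed,
        )
    else:
        rt = diversity.rarefy(
            state["table"], depth=cfg.depth, n_rep=cfg.n_rep, seed=cfg.seed
        )
        rt.table.to_tsv(counts_p, meta_p)
    logger.info(
        "rarefied to %d reads; %d sample(s) excluded: %s",
        cfg.depth,
        len(rt.excluded_samples),
        rt.excluded_samples or "-",
    )
    state["rarefied"] = rt
    state["relabund"] = rt.table.relative_abundances()
    state["summary"]["n_samples_rarefied"] = rt.table.n_samples
    state["summary"]["excluded_samples"] = rt.excluded_samples


def _stage_diversity(config: PipelineConfig, out: Path, state: dict) -> None:
    path = out / "alpha_diversity.tsv"
    if config.resume and path.exists():
        alpha = pd.read_csv(path, sep="\t", index_col="sample_id")
    else:
        cfg = config.rarefaction
        alpha = diversity.mean_alpha_diversity(
            state["table"], depth=cfg.depth, n_rep=cfg.n_rep, seed=cfg.seed
        )
        alpha.to_csv(path, sep="\t")
    state["alpha"] = alpha


def _stage_ordination(config: PipelineConfig, out: Path, state: dict) -> None:
    rt = state["rarefied"]
    D = diversity.bray_curtis(rt.table)
    ord_res = diversity.pcoa(D)
    baseline = diversity.distance_from_baseline(D, rt.table.metadata)
    D.write(str(out / "bray_curtis.tsv"))
    coords = ord_res.coordinates.copy()
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        {
            "eigenvalue": ord_res.eigenvalues[: len(ord_res.proportion_explained)],
            "proportion_explained": ord_res.proportion_explained,
        }
    ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    baseline.to_csv(out / "distance_to_baseline.tsv", sep="\t")
    state["distance"] = D
    state["baseline"] = baseline
    shift = (
        baseline.groupby(["group", "day"])["distance_to_baseline"]
        .mean()
        .reset_index()
    )
    state["summary"]["baseline_shift"] = shift.to_dict(orient="records")


def _stage_permanova(config: PipelineConfig, out: Path, state: dict) -> None:
    cfg = config.permanova
    meta = state["rarefied"].table.metadata
    if config.contrasts:
        contrasts = [
            ((a, int(da)), (b, int(db))) for a, da, b, db in config.contrasts
        ]
    else:
        contrasts = default_contrasts(meta)
    screen = permanova.pairwise_screen(
        state["distance"],
        meta,
        contrasts,
        alpha=cfg.alpha,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    screen.to_csv(out / "permanova_screen.tsv", sep="\t", index=False)
    state["contrasts"] = contrasts
    state["screen"] = screen
    state["summary"]["permanova_screen"] = [
        {"contrast": r.contrast, "p": r.p_value, "significant": bool(r.significant)}
        for r in screen.itertuples()
    ]


def _stage_keyotu(config: PipelineConfig, out: Path, state: dict) -> None:
    cfg = config.keyotu
    screen = state["screen"]
    rel = state["relabund"]
    meta = state["rarefied"].table.metadata
    rng = np.random.default_rng(cfg.seed)
    models = []
    rows = []
    for rec in screen.itertuples():
        model_seed = int(rng.integers(2**31 - 1))
        if not rec.significant:
            continue
        ids_a = meta.index[
            (meta["group"] == rec.group_a) & (meta["day"] == rec.day_a)
        ]
        ids_b = meta.index[
            (meta["group"] == rec.group_b) & (meta["day"] == rec.day_b)
        ]
        ids = list(ids_a) + list(ids_b)
        labels = pd.Series(
            ["a"] * len(ids_a) + ["b"] * len(ids_b), index=ids
        )
        model = keyotu.fit_pair_model(
            rel.loc[ids],
            labels,
            n_trees=cfg.n_trees,
            seed=model_seed,
            pair=rec.contrast,
        )
        models.append(model)
        for otu, mda in model.importance.items():
            rows.append(
                {
                    "pair": model.pair,
                    "oob_class_error": model.oob_class_error,
                    "otu": otu,
                    "mda": mda,
                }
            )
    pd.DataFrame(rows).to_csv(out / "pair_models.tsv", sep="\t", index=False)
    key = keyotu.select_key_otus(
        models, mda_threshold=cfg.mda_threshold, max_class_error=cfg.max_class_error
    )
    pd.DataFrame(
        {
            "otu": key.otu_ids,
            "models": [";".join(key.provenance[o]) for o in key.otu_ids],
        }
    ).to_csv(out / "key_otus.tsv", sep="\t", index=False)
    logger.info(
        "%d/%d models successful; %d key OTUs",
        sum(m.oob_class_error <= cfg.max_class_error for m in models),
        len(models),
        len(key),
    )
    state["models"] = models
    state["key_otus"] = key
    state["summary"]["n_key_otus"] = len(key)
    state["summary"]["key_otus"] = key.otu_ids


def _stage_sparcc(config: PipelineConfig, out: Path, state: dict) -> None:
    cfg = config.sparcc
    rt = state["rarefied"]
    key = state["key_otus"]
    otus = list(key.otu_ids)
    inv = config.invader_otu
    if inv and inv in rt.table.otu_ids and inv not in otus:
        otus.append(inv)  # the invader always enters the correlation panel
    if len(otus) < 4:
        raise ValueError(
            f"only {len(otus)} key OTUs; SparCC needs at least 4 taxa"
        )
    counts = rt.table.counts[otus]
    result = sparcc.sparcc_estimate(
        counts,
        n_est_iter=cfg.n_est_iter,
        exclusion_threshold=cfg.exclusion_threshold,
        max_exclusions=cfg.max_exclusions,
        seed=cfg.seed,
    )
    result.p_values = sparcc.sparcc_null_pvalues(
        counts,
        result.rho,
        n_null=cfg.n_null,
        seed=cfg.seed + 1,
        n_est_iter=cfg.null_est_iter,
        exclusion_threshold=cfg.exclusion_threshold,
        max_exclusions=cfg.max_exclusions,
    )
    result.n_null = cfg.n_null
    result.rho.to_csv(out / "sparcc_rho.tsv", sep="\t", index_label="otu")
    result.p_values.to_csv(out / "sparcc_p.tsv", sep="\t", index_label="otu")
    mean_ab = state["relabund"][otus].mean()
    g = sparcc.build_network(
        result, edge_threshold=cfg.edge_threshold, mean_abundance=mean_ab
    )
    sparcc.network_edge_list(g).to_csv(
        out / "network_edges.tsv", sep="\t", index=False
    )
    nx.write_graphml(g, out / "network.graphml")
    state["sparcc"] = result
    state["summary"]["n_network_edges"] = g.number_of_edges()


def _stage_cag(config: PipelineConfig, out: Path, state: dict) -> None:
    cfg = config.cag
    result = state["sparcc"]
    assignment = cagmod.cluster_cags(
        result, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed
    )
    df = assignment.assignment.rename_axis("otu").reset_index()
    df.to_csv(out / "cag_assignment.tsv", sep="\t", index=False)
    (out / "cag_dendrogram.nwk").write_text(assignment.to_newick() + "\n")
    profile = cagmod.cag_abundance_profiles(state["relabund"], assignment)
    profile.to_csv(out / "cag_profiles.tsv", sep="\t", index_label="sample_id")
    meta = state["rarefied"].table.metadata
    dynamics = cagmod.cag_group_dynamics(
        profile, meta, reference_group=cfg.reference_group
    )
    dynamics.to_csv(out / "cag_dynamics.tsv", sep="\t", index=False)
    state["cags"] = assignment
    state["dynamics"] = dynamics
    state["summary"]["n_cags"] = int(assignment.n_cags)
    inv = config.invader_otu
    if inv and inv in result.rho.index:
        pos, neg = cagmod.invader_correlates(result, inv)
        state["summary"]["invader_positive_correlates"] = sorted(pos)
        state["summary"]["invader_negative_correlates"] = sorted(neg)


def _stage_differential(config: PipelineConfig, out: Path, state: dict) -> None:
    rt = state["rarefied"]
    alpha = config.differential.alpha_fdr
    n_sig = {}
    for cell_a, cell_b in state["contrasts"]:
        name = f"{cell_a[0]}@d{cell_a[1]}_vs_{cell_b[0]}@d{cell_b[1]}"
        results = differential_otus(rt.table, None, cell_a, cell_b, alpha_fdr=alpha)
        frame = results_to_frame(results)
        frame.to_csv(out / f"differential_{name}.tsv", sep="\t")
        sig = frame[frame["significant"]]
        n_sig[name] = {
            "enriched": int((sig["direction"] == "enriched").sum()),
            "depleted": int((sig["direction"] == "depleted").sum()),
        }
    state["summary"]["differential"] = n_sig


def _stage_summary(config: PipelineConfig, out: Path, state: dict) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(state["summary"], fh, indent=2, default=str)


_STAGES = {
    "input": _stage_input,
    "rarefy": _stage_rarefy,
    "diversity": _stage_diversity,
    "ordination": _stage_ordination,
    "permanova": _stage_permanova,
    "keyotu": _stage_keyotu,
    "sparcc": _stage_sparcc,
    "cag": _stage_cag,
    "differential": _stage_differential,
    "summary": _stage_summary,
}
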