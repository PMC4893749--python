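"""Synthetic longitudinal 16S cohorts with known planted structure.

The generator emulates a 3-group (PBS control, DSS colitis, DSS plus a
gavaged butyrate-producer "invader") x 4-timepoint mouse study. Latent
per-sample log-abundances follow a logistic-normal model with
block-structured correlation; group-by-day log-fold effects deplete or
enrich whole blocks, the invader group's effects run a configurable
number of days ahead of the plain-disease group (an accelerated
community shift), and the invader itself is an extra taxon present only
in inoculated groups. Counts are multinomial draws at a random depth,
so taxa are compositionally entangled exactly as real amplicon counts
are. The planted structure is returned as a GroundTruth object and is
the recovery oracle for every downstream stage.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .containers import OtuTable
from .readqc import FastqRead, reverse_complement

LN2 = math.log(2.0)

GROUP_PBS = "PBS"
GROUP_DSS = "DSS"
GROUP_INVADER = "DSS+BPB5"
INVADER_OTU_ID = "OTU_BPB5"


@dataclasses.dataclass
class StudyDesign:
    """Sampling layout: which groups were sampled on which days, how often."""

    groups: list[str]
    days: list[int]
    n_samples: dict[tuple[str, int], int]
    n_otus: int = 100
    depth_range: tuple[int, int] = (9000, 30000)

    def __post_init__(self) -> None:
        if sorted(self.days) != list(self.days) or len(set(self.days)) != len(
            self.days
        ):
            raise ValueError("days must be strictly increasing")
        for g in self.groups:
            for d in self.days:
                if self.n_samples.get((g, d), 0) < 1:
                    raise ValueError(f"missing or zero sample size for {(g, d)}")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth range")

    @property
    def total_samples(self) -> int:
        return sum(self.n_samples[(g, d)] for g in self.groups for d in self.days)


def build_default_design() -> StudyDesign:
    """The study's default layout: 3 groups x days {-1, 2, 4, 7}.

    Per-cell sample sizes follow the published cohort: 12/11/12/6 for
    the invader group, 12/12/12/6 for DSS, 12/10/12/6 for PBS (123
    samples in total; per-day attrition is taken as fixed, not
    simulated).
    """
    days = [-1, 2, 4, 7]
    sizes = {
        GROUP_PBS: [12, 10, 12, 6],
        GROUP_DSS: [12, 12, 12, 6],
        GROUP_INVADER: [12, 11, 12, 6],
    }
    n_samples = {
        (g, d): n for g, per in sizes.items() for d, n in zip(days, per)
    }
    return StudyDesign(
        groups=[GROUP_PBS, GROUP_DSS, GROUP_INVADER],
        days=days,
        n_samples=n_samples,
    )


@dataclasses.dataclass
class EffectSpec:
    """Planted biology: correlated blocks, treatment effects, the invader.

    Effects are log2 fold changes applied on the latent log scale; they
    ramp linearly from DSS start (day 0) to ``full_effect_day`` and, in
    invader groups, run ``shift_lead_days`` days ahead of that schedule.
    """

    n_blocks: int = 5
    block_size: int = 10
    within_block_corr: float = 0.8
    depleted_blocks: tuple[int, ...] = (0, 1)
    enriched_blocks: tuple[int, ...] = (2, 3)
    invader_led_blocks: tuple[int, ...] = (3,)
    effect_log2_fold: float = 4.0
    affected_groups: tuple[str, ...] = (GROUP_DSS, GROUP_INVADER)
    invader_groups: tuple[str, ...] = (GROUP_INVADER,)
    invader_otu: str = INVADER_OTU_ID
    invader_base_log: float = 0.5
    invader_rise_log: float = 2.0
    shift_lead_days: int = 3
    dss_start_day: int = 0
    full_effect_day: int = 7
    latent_sd: float = 1.0
    subject_sd: float = 0.25
    baseline_mean_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must be in [0, 1)")
        bad = set(self.invader_led_blocks) - set(self.enriched_blocks) - set(
            self.depleted_blocks
        )
        if bad:
            raise ValueError("invader-led blocks must be effect blocks")

    def block_assignments(self, n_otus: int) -> np.ndarray:
        """Block id per OTU; -1 marks uncorrelated background taxa."""
        n_structured = self.n_blocks * self.block_size
        if n_structured > n_otus:
            raise ValueError("n_otus too small for the requested blocks")
        blocks = np.full(n_otus, -1, dtype=int)
        for b in range(self.n_blocks):
            blocks[b * self.block_size : (b + 1) * self.block_size] = b
        return blocks

    def ramp(self, day: int, group: str) -> float:
        """Effect multiplier in [0, 1]; invader groups run ahead by the lead."""
        if day < self.dss_start_day:
            return 0.0
        t = day + (self.shift_lead_days if group in self.invader_groups else 0)
        span = self.full_effect_day - self.dss_start_day
        return min(max(t - self.dss_start_day, 0), span) / span

    def latent_shift(self, group: str, day: int, n_otus: int) -> np.ndarray:
        """Per-OTU latent (natural-log) shift for one group-day cell."""
        shift = np.zeros(n_otus)
        if group not in self.affected_groups:
            return shift
        r = self.ramp(day, group)
        effect_ln = self.effect_log2_fold * LN2
        blocks = self.block_assignments(n_otus)
        for b in self.depleted_blocks:
            shift[blocks == b] = -effect_ln * r
        for b in self.enriched_blocks:
            shift[blocks == b] = effect_ln * r
        return shift

    def invader_latent(self, group: str, day: int) -> float:
        """Latent log-abundance of the invader; -inf when not inoculated."""
        if group not in self.invader_groups:
            return -np.inf
        return self.invader_base_log + self.invader_rise_log * self.ramp(
            day, group
        )


@dataclasses.dataclass
class GroundTruth:
    """Planted structure returned next to every simulated table."""

    block_assignments: pd.Series
    discriminatory_otus: dict[tuple[str, str], set[str]]
    invader_otu: str | None
    invader_correlates: set[str]
    latent_fractions: pd.DataFrame


def simulate_otu_table(
    design: StudyDesign, effects: EffectSpec, seed: int
) -> tuple[OtuTable, GroundTruth]:
    """Draw a full cohort count table plus its ground truth.

    Latent logs are mean + group-day shift + subject offset + block-
    correlated noise (one-factor model per block, unit total variance
    scaled by ``latent_sd``); fractions are the softmax of the latent
    logs including the invader where inoculated; counts are multinomial
    at a depth uniform over ``depth_range``. Identical arguments and
    seed give identical output.
    """
    if design.n_otus < 4:
        raise ValueError("need at least 4 OTUs (SparCC requires >= 4 taxa)")
    rng = np.random.default_rng(seed)
    p = design.n_otus
    otu_ids = [f"OTU{i + 1:03d}" for i in range(p)]
    blocks = effects.block_assignments(p)
    base_mean = rng.normal(0.0, effects.baseline_mean_sd, size=p)

    has_invader = bool(effects.invader_groups)
    all_otu_ids = otu_ids + ([effects.invader_otu] if has_invader else [])

    # per-subject intercepts, persistent across days (longitudinal design)
    subj_offsets: dict[str, np.ndarray] = {}
    led = np.isin(blocks, effects.invader_led_blocks)

    rows, metas, latent_rows, ids = [], [], [], []
    rho = effects.within_block_corr
    sq_r, sq_1mr = math.sqrt(rho), math.sqrt(1.0 - rho)
    for group in design.groups:
        n_subjects = max(design.n_samples[(group, d)] for d in design.days)
        for subj_i in range(n_subjects):
            subj = f"{group}_m{subj_i + 1:02d}"
            subj_offsets[subj] = rng.normal(0.0, effects.subject_sd, size=p)
        for day in design.days:
            n = design.n_samples[(group, day)]
            shift = effects.latent_shift(group, day, p)
            inv_latent = effects.invader_latent(group, day)
            for i in range(n):
                subj = f"{group}_m{i + 1:02d}"
                z_block = rng.normal(size=max(effects.n_blocks, 1))
                eps = rng.normal(size=p)
                noise = np.where(
                    blocks >= 0,
                    sq_r * z_block[np.clip(blocks, 0, None)] + sq_1mr * eps,
                    eps,
                )
                latent = (
                    base_mean
                    + shift
                    + subj_offsets[subj]
                    + effects.latent_sd * noise
                )
                latent_all = latent
                if has_invader:
                    if np.isfinite(inv_latent):
                        led_factor = (
                            z_block[effects.invader_led_blocks[0]]
                            if effects.invader_led_blocks
                            else rng.normal()
                        )
                        inv_noise = sq_r * led_factor + sq_1mr * rng.normal()
                        inv_val = inv_latent + effects.latent_sd * inv_noise
                    else:
                        rng.normal()  # keep the stream aligned across groups
                        inv_val = -np.inf
                    latent_all = np.append(latent, inv_val)
                ex = np.exp(latent_all - latent_all[np.isfinite(latent_all)].max())
                frac = ex / ex.sum()
                depth = int(
                    rng.integers(design.depth_range[0], design.depth_range[1] + 1)
                )
                counts = rng.multinomial(depth, frac)
                sample_id = f"{group}_d{day}_s{i + 1:02d}"
                ids.append(sample_id)
                rows.append(counts)
                latent_rows.append(frac)
                metas.append({"group": group, "day": day, "subject": subj})

    counts_df = pd.DataFrame(rows, index=ids, columns=all_otu_ids)
    meta_df = pd.DataFrame(metas, index=ids)
    table = OtuTable(counts=counts_df, metadata=meta_df)

    effect_otus = {
        otu_ids[i]
        for i in range(p)
        if blocks[i] in effects.depleted_blocks + effects.enriched_blocks
    }
    disc: dict[tuple[str, str], set[str]] = {}
    for g1 in design.groups:
        for g2 in design.groups:
            if g1 >= g2:
                continue
            a1 = g1 in effects.affected_groups
            a2 = g2 in effects.affected_groups
            lead1 = g1 in effects.invader_groups
            lead2 = g2 in effects.invader_groups
            s: set[str] = set()
            if a1 != a2 or (a1 and a2 and lead1 != lead2):
                s |= effect_otus
            if has_invader and lead1 != lead2:
                s.add(effects.invader_otu)
            disc[(g1, g2)] = s

    truth = GroundTruth(
        block_assignments=pd.Series(blocks, index=otu_ids, name="block"),
        discriminatory_otus=disc,
        invader_otu=effects.invader_otu if has_invader else None,
        invader_correlates={otu_ids[i] for i in range(p) if led[i]},
        latent_fractions=pd.DataFrame(
            latent_rows, index=ids, columns=all_otu_ids
        ),
    )
    return table, truth


# ----------------------------------------------------------- paired reads


@dataclasses.dataclass
class QualityModel:
    """Per-position Phred profiles for the forward and reverse reads."""

    fwd: np.ndarray
    rev: np.ndarray

    @classmethod
    def flat(cls, q: int, read_length: int) -> "QualityModel":
        prof = np.full(read_length, q, dtype=int)
        return cls(fwd=prof.copy(), rev=prof.copy())


def make_otu_sequences(n_otus: int, length: int, seed: int) -> dict[str, str]:
    """Random amplicon templates (>= 430 bases recommended)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        f"OTU{i + 1:03d}": "".join(rng.choice(bases, size=length))
        for i in range(n_otus)
    }


def _truncation_length(quals: np.ndarray, qmax: int = 2) -> int:
    hits = np.nonzero(np.asarray(quals) <= qmax)[0]
    return int(hits[0]) if hits.size else len(quals)


def simulate_paired_reads(
    otu_sequences: dict[str, str],
    sample_counts: dict[str, int],
    quality_model: QualityModel,
    seed: int,
    qmax: int = 2,
    min_overlap: int = 50,
    max_mismatch_frac: float = 0.1,
    min_len: int = 400,
    max_ee: float = 0.5,
) -> tuple[list[FastqRead], list[FastqRead], dict[str, bool]]:
    """Simulate paired reads off templates plus the expected QC verdicts.

    Forward reads copy the template 5' end, reverse reads the
    reverse-complemented 3' end; read lengths come from the quality
    profiles and must leave a positive overlap. Substitution errors are
    drawn per base at the Phred-implied rate 10^(-Q/10). ``expected_pass``
    is derived directly from the planted qualities and planted errors by
    the QC rules (Q<=qmax truncation, >= ``min_overlap`` merge with
    <= ``max_mismatch_frac`` overlap mismatches, merged length >=
    ``min_len``, EE <= ``max_ee``), independently of the QC code path.
    """
    rng = np.random.default_rng(seed)
    qf = np.asarray(quality_model.fwd, dtype=int)
    qr = np.asarray(quality_model.rev, dtype=int)
    lf, lr = len(qf), len(qr)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    fwd_reads: list[FastqRead] = []
    rev_reads: list[FastqRead] = []
    expected: dict[str, bool] = {}
    counter = 0
    for otu, count in sample_counts.items():
        template = otu_sequences[otu]
        T = len(template)
        if T < 430:
            raise ValueError("templates must be >= 430 bases")
        if lf > T or lr > T:
            raise ValueError("read length exceeds template length")
        if lf + lr - T < 1:
            raise ValueError("reads must overlap by at least 1 base")
        tarr = np.frombuffer(template.encode(), dtype=np.uint8)
        for _ in range(count):
            counter += 1
            rid = f"read{counter:06d}_{otu}"
            f_true = tarr[:lf].copy()
            r_true_fragment = tarr[T - lr :]

            perr_f = 10.0 ** (-qf / 10.0)
            perr_r = 10.0 ** (-qr / 10.0)
            f_obs = f_true.copy()
            err_f = rng.random(lf) < perr_f
            for pos in np.nonzero(err_f)[0]:
                alt = bases[bases != f_obs[pos]]
                f_obs[pos] = rng.choice(alt)
            # reverse read in read orientation: revcomp of 3' fragment
            r_read_true = np.frombuffer(
                reverse_complement(r_true_fragment.tobytes().decode()).encode(),
                dtype=np.uint8,
            ).copy()
            r_obs = r_read_true.copy()
            err_r = rng.random(lr) < perr_r
            for pos in np.nonzero(err_r)[0]:
                alt = bases[bases != r_obs[pos]]
                r_obs[pos] = rng.choice(alt)

            fwd_reads.append(
                FastqRead(id=rid, bases=f_obs.tobytes().decode(), quals=qf.copy())
            )
            rev_reads.append(
                FastqRead(id=rid, bases=r_obs.tobytes().decode(), quals=qr.copy())
            )

            expected[rid] = _expected_verdict(
                f_obs,
                r_obs,
                qf,
                qr,
                T,
                qmax=qmax,
                min_overlap=min_overlap,
                max_mismatch_frac=max_mismatch_frac,
                min_len=min_len,
                max_ee=max_ee,
            )
    return fwd_reads, rev_reads, expected


def _expected_verdict(
    f_obs: np.ndarray,
    r_obs: np.ndarray,
    qf: np.ndarray,
    qr: np.ndarray,
    T: int,
    qmax: int,
    min_overlap: int,
    max_mismatch_frac: float,
    min_len: int,
    max_ee: float,
) -> bool:
    """Re-derive the QC verdict arithmetically from planted arrays.

    Works in template coordinates at the true layout, so it never calls
    the QC module's offset scan or merger.
    """
    len_f = _truncation_length(qf, qmax)
    len_r = _truncation_length(qr, qmax)
    if len_f == 0 or len_r == 0:
        return False
    # truncated reverse read covers template positions [T - len_r, T)
    overlap = len_f + len_r - T
    if overlap < min_overlap:
        return False
    # observed bases on template coordinates; the revcomp'd reverse read
    # spans template [T - lr, T), so template position p maps to index
    # p - (T - lr) within it
    lr = len(qr)
    r_on_template = np.frombuffer(
        reverse_complement(r_obs.tobytes().decode()).encode(), dtype=np.uint8
    )
    ov_f = f_obs[T - len_r : len_f]
    ov_r = r_on_template[lr - len_r : len_f - (T - lr)]
    mism = int((ov_f != ov_r).sum())
    if mism / overlap > max_mismatch_frac:
        return False
    merged_len = len_f + len_r - overlap
    if merged_len < min_len:
        return False
    # merged quals: fwd-only prefix, max(Q) in overlap, rev-only suffix
    q_template_rev = qr[::-1]  # template position T - lr + i has qr rev
    q_rev_full = np.full(T, -1, dtype=int)
    q_rev_full[T - len(qr) :] = q_template_rev
    q_fwd_full = np.full(T, -1, dtype=int)
    q_fwd_full[: len(qf)] = qf
    q_fwd_full[len_f:] = -1
    keep_rev = np.full(T, False)
    keep_rev[T - len_r :] = True
    merged_q = np.where(
        keep_rev & (q_rev_full > q_fwd_full), q_rev_full, q_fwd_full
    )
    merged_q = merged_q[merged_q >= 0]
    return expected_error(merged_q) <= max_ee


def expected_error(quals) -> float:
    """Sum of Phred-implied per-base error probabilities."""
    quals = np.asarray(quals, dtype=float)
    return float(np.sum(10.0 ** (-quals / 10.0)))
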