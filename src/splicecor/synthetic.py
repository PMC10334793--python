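"""Synthetic cohorts and perturbation experiments with the statistical
structure the downstream analysis assumes.

The cohort generator emulates a multi-stage disease spectrum: each sample
carries a latent pathway activity a_i drawn Normal(stage mean, stage sd),
with stage means increasing along the spectrum (normal -> benign ->
tumor). Pathway genes respond with mean count mu_g * 2^(beta_g * a_i);
background genes are activity-independent. Cassette-exon inclusion is
coupled to activity through a logit link, psi_i = logistic(b0 + b1*a_i)
(b1 = 0 for null events); per-event total junction reads are negative
binomial and inclusion reads binomial with the length-biased read
probability q = psi*lI / (psi*lI + (1-psi)*lS).

All randomness flows through one numpy Generator per call, seeded
explicitly; the same seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datatypes import CountsMatrix, SampleMetadata, SeEventTable, SpliceCorError

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "default_cohort_config",
    "simulate_cohort",
    "simulate_two_group_experiment",
    "simulate_sequence_with_gruns",
]

logger = logging.getLogger(__name__)

#: default disease spectrum: latent activity rises with progression
DEFAULT_STAGES = [
    ("normal", 100, 0.0, 0.5),
    ("benign", 100, 1.0, 0.5),
    ("tumor", 100, 2.0, 0.5),
]


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    stages: ordered (label, n_samples, activity_mean, activity_sd) tuples.
    pathway_response: log2-fold expression change per unit activity,
        scalar (shared) or one beta_g per pathway gene.
    coupled_events: (event_index, b0, b1) triples on the logit-PSI scale;
        events not listed are null (b1 = 0, b0 drawn from null_b0_range).
    coverage_mean / coverage_dispersion: negative-binomial parameters of
        per-event total junction reads (variance = mu + mu^2/theta).
    inc_form_len / skip_form_len: effective form lengths (defaults match
        typical rMATS values for 100-nt reads).
    """

    seed: int = 0
    stages: list = field(default_factory=lambda: list(DEFAULT_STAGES))
    n_pathway_genes: int = 50
    n_background_genes: int = 200
    pathway_response: float | list = 1.0
    n_events: int = 500
    coupled_events: list = field(default_factory=list)
    coverage_mean: float = 100.0
    coverage_dispersion: float = 10.0
    inc_form_len: int = 198
    skip_form_len: int = 99
    gene_dispersion: float = 10.0
    baseline_log10_counts: tuple = (2.0, 3.0)
    null_b0_range: tuple = (-1.5, 1.5)
    cohort_name: str = "SYN"

    def __post_init__(self):
        for name, v in [("n_pathway_genes", self.n_pathway_genes),
                        ("n_background_genes", self.n_background_genes),
                        ("n_events", self.n_events)]:
            if v < 1:
                raise SpliceCorError(f"{name} must be >= 1")
        if not self.stages:
            raise SpliceCorError("at least one stage required")
        for label, n, mu, sd in self.stages:
            if n < 1:
                raise SpliceCorError(f"stage {label!r} has n_samples = {n}; must be >= 1")
            if sd <= 0:
                raise SpliceCorError(f"stage {label!r} has activity_sd = {sd}; must be > 0")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise SpliceCorError("coverage_mean and coverage_dispersion must be > 0")
        if self.inc_form_len < 1 or self.skip_form_len < 1:
            raise SpliceCorError("effective form lengths must be >= 1")
        for idx, b0, b1 in self.coupled_events:
            if not (0 <= idx < self.n_events):
                raise SpliceCorError(f"coupled event index {idx} out of range")
        beta = np.atleast_1d(np.asarray(self.pathway_response, dtype=float))
        if beta.size not in (1, self.n_pathway_genes):
            raise SpliceCorError("pathway_response must be a scalar or one beta per pathway gene")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n, _, _ in self.stages)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = [tuple(s) for s in d["stages"]]
        if "coupled_events" in d:
            d["coupled_events"] = [tuple(e) for e in d["coupled_events"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside simulated outputs for parameter recovery."""

    activity: pd.Series  # latent a_i per sample (cohort simulations)
    event_params: pd.DataFrame  # event_id, b0, b1, coupled
    psi_group1: np.ndarray | None = None  # two-group designs
    psi_group2: np.ndarray | None = None
    changed: np.ndarray | None = None

    @property
    def coupled_event_ids(self) -> list:
        return list(self.event_params.loc[self.event_params["coupled"], "event_id"])

    def to_json_dict(self) -> dict:
        out = {
            "activity": {str(k): float(v) for k, v in self.activity.items()},
            "event_params": self.event_params.to_dict(orient="records"),
        }
        if self.psi_group1 is not None:
            out["psi_group1"] = [float(v) for v in self.psi_group1]
            out["psi_group2"] = [float(v) for v in self.psi_group2]
            out["changed"] = [bool(v) for v in self.changed]
        return out


def default_cohort_config(seed: int = 0, n_coupled: int = 25,
                          b1_range: tuple = (-2.0, -0.5), **overrides) -> CohortConfig:
    """A CohortConfig with randomly placed activity-coupled events.

    Coupled slopes b1 are drawn uniformly from ``b1_range`` (negative by
    default: inclusion repressed as activity rises, the direction of a
    pathway-repressed poison exon). Intercepts are centered so the PSI
    dynamic range straddles the cohort's mean activity:
    b0 = -b1 * mean_activity + Uniform(-0.5, 0.5).
    """
    cfg = CohortConfig(seed=seed, **overrides)
    if n_coupled > cfg.n_events:
        raise SpliceCorError("more coupled events than events")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    idx = rng.choice(cfg.n_events, size=n_coupled, replace=False)
    total = cfg.n_samples
    mean_act = sum(n * mu for _, n, mu, _ in cfg.stages) / total
    lo, hi = b1_range
    b1 = rng.uniform(lo, hi, size=n_coupled)
    b0 = -b1 * mean_act + rng.uniform(-0.5, 0.5, size=n_coupled)
    cfg.coupled_events = [(int(i), float(a), float(b)) for i, a, b in zip(idx, b0, b1)]
    return cfg


def _rnegbin(rng, mean, theta):
    """Negative binomial draws parameterized by mean and dispersion theta."""
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p, size=mean.shape)


def _event_geometry(n_events: int) -> pd.DataFrame:
    idx = np.arange(n_events)
    start = 10_000 + idx * 5_000
    return pd.DataFrame({
        "event_id": [f"EV{i + 1:05d}" for i in idx],
        "gene_id": [f"GENE{i + 1:05d}" for i in idx],
        "gene_symbol": [f"Sym{i + 1}" for i in idx],
        "chrom": [f"chr{(i % 22) + 1}" for i in idx],
        "strand": np.where(idx % 2 == 0, "+", "-"),
        "exon_start": start,
        "exon_end": start + 82,
        "upstream_es": start - 600,
        "upstream_ee": start - 450,
        "downstream_es": start + 82 + 450,
        "downstream_ee": start + 82 + 600,
    })


def _sample_junction_counts(rng, psi, coverage_mean, theta, lI, lS):
    """Total reads ~ NB, inclusion reads ~ Binomial(T, q(psi)); returns (I, S)."""
    total = _rnegbin(rng, np.full(psi.shape, coverage_mean), theta)
    q = psi * lI / (psi * lI + (1 - psi) * lS)
    inc = rng.binomial(total, q)
    return inc.astype(float), (total - inc).astype(float)


def simulate_cohort(config: CohortConfig):
    """Simulate one cohort: counts, metadata, junction-count table, and truth.

    Returns (CountsMatrix, SampleMetadata, SeEventTable, SyntheticTruth).
    Identical config (including seed) gives byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # latent activity per sample, stage by stage
    sample_ids, stage_labels, activity = [], [], []
    for label, n_s, mu, sd in config.stages:
        start = len(sample_ids)
        sample_ids += [f"{config.cohort_name}_{label}_{i + 1:04d}" for i in range(n_s)]
        stage_labels += [label] * n_s
        activity.append(rng.normal(mu, sd, size=n_s))
    a = np.concatenate(activity)

    # gene expression counts
    beta = np.atleast_1d(np.asarray(config.pathway_response, dtype=float))
    if beta.size == 1:
        beta = np.full(config.n_pathway_genes, beta[0])
    lo, hi = config.baseline_log10_counts
    n_genes = config.n_pathway_genes + config.n_background_genes
    mu_g = 10 ** rng.uniform(lo, hi, size=n_genes)
    mean_mat = np.tile(mu_g[:, None], (1, n))
    mean_mat[: config.n_pathway_genes] *= 2.0 ** (beta[:, None] * a[None, :])
    counts = _rnegbin(rng, mean_mat, config.gene_dispersion)
    gene_ids = [f"PWY{i + 1:04d}" for i in range(config.n_pathway_genes)] + [
        f"BG{i + 1:04d}" for i in range(config.n_background_genes)
    ]

    # event PSI curves
    b0 = rng.uniform(*config.null_b0_range, size=config.n_events)
    b1 = np.zeros(config.n_events)
    coupled = np.zeros(config.n_events, dtype=bool)
    for idx, b0_i, b1_i in config.coupled_events:
        b0[idx], b1[idx], coupled[idx] = b0_i, b1_i, True
    logit = b0[:, None] + b1[:, None] * a[None, :]
    psi = 1.0 / (1.0 + np.exp(-logit))

    ijc, sjc = _sample_junction_counts(
        rng, psi, config.coverage_mean, config.coverage_dispersion,
        config.inc_form_len, config.skip_form_len,
    )

    counts_mat = CountsMatrix(gene_ids, sample_ids, counts)
    meta = SampleMetadata(pd.DataFrame(
        {"cohort": config.cohort_name, "stage": stage_labels},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    events = _event_geometry(config.n_events)
    table = SeEventTable(
        events, sample_ids, ijc, sjc,
        np.full(config.n_events, float(config.inc_form_len)),
        np.full(config.n_events, float(config.skip_form_len)),
        genome_build="synthetic",
    )
    truth = SyntheticTruth(
        activity=pd.Series(a, index=sample_ids, name="activity"),
        event_params=pd.DataFrame({
            "event_id": events["event_id"], "b0": b0, "b1": b1, "coupled": coupled,
        }),
    )
    return counts_mat, meta, table, truth


def simulate_two_group_experiment(
    n_per_group: int,
    n_events: int,
    n_changed: int,
    delta_psi: float,
    coverage: float,
    seed: int = 0,
    coverage_dispersion: float = 10.0,
    inc_form_len: int = 198,
    skip_form_len: int = 99,
):
    """Two-group (control vs perturbation) experiment with planted PSI shifts.

    Group-1 baseline PSI is Uniform(0.1, 0.9); for the first ``n_changed``
    events group 2 is shifted by +/- delta_psi (random sign), clamped to
    [0.01, 0.99]. Baselines whose clamping would erode the planted shift
    are resampled (a notice is logged). Counts are sampled as in
    simulate_cohort. Returns (SeEventTable, SampleMetadata, SyntheticTruth).
    """
    if not (0 < delta_psi <= 1):
        raise SpliceCorError("delta_psi must be in (0, 1]")
    if n_changed > n_events:
        raise SpliceCorError("n_changed cannot exceed n_events")
    if n_per_group < 1:
        raise SpliceCorError("need >= 1 sample per group")

    rng = np.random.default_rng(seed)
    psi1 = rng.uniform(0.1, 0.9, size=n_events)
    psi2 = psi1.copy()
    changed = np.zeros(n_events, dtype=bool)
    changed[:n_changed] = True
    for e in range(n_changed):
        for attempt in range(1000):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shifted = float(np.clip(psi1[e] + sign * delta_psi, 0.01, 0.99))
            if abs(shifted - psi1[e]) >= delta_psi - 1e-9:
                psi2[e] = shifted
                break
            logger.info("event %d: clamping erased the planted shift; resampling baseline", e)
            psi1[e] = rng.uniform(0.1, 0.9)
        else:
            raise SpliceCorError(f"could not place a +/-{delta_psi} shift for event {e}")

    n_total = 2 * n_per_group
    psi = np.concatenate(
        [np.tile(psi1[:, None], (1, n_per_group)), np.tile(psi2[:, None], (1, n_per_group))],
        axis=1,
    )
    ijc, sjc = _sample_junction_counts(
        rng, psi, coverage, coverage_dispersion, inc_form_len, skip_form_len
    )

    sample_ids = [f"G1_S{i + 1}" for i in range(n_per_group)] + [
        f"G2_S{i + 1}" for i in range(n_per_group)
    ]
    meta = SampleMetadata(pd.DataFrame(
        {"cohort": "EXP", "condition": ["control"] * n_per_group + ["ko"] * n_per_group},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    events = _event_geometry(n_events)
    table = SeEventTable(
        events, sample_ids, ijc, sjc,
        np.full(n_events, float(inc_form_len)),
        np.full(n_events, float(skip_form_len)),
        genome_build="synthetic",
    )
    truth = SyntheticTruth(
        activity=pd.Series(np.zeros(n_total), index=sample_ids, name="activity"),
        event_params=pd.DataFrame({
            "event_id": events["event_id"],
            "b0": np.log(psi1 / (1 - psi1)),
            "b1": 0.0,
            "coupled": changed,
        }),
        psi_group1=psi1,
        psi_group2=psi2,
        changed=changed,
    )
    return table, meta, truth


def simulate_sequence_with_gruns(length: int, g_run_lengths: list, seed: int = 0):
    """A random {A,C,T} background with maximal G-runs of the requested
    lengths planted at recorded positions.

    The background contains no G at all, so every planted run is maximal
    by construction, and runs are separated by at least one non-G base.
    Returns (sequence, [(start, end), ...]) with intervals in plant order
    (ascending by start).

    >>> seq, spans = simulate_sequence_with_gruns(50, [3, 4], seed=1)
    >>> [seq[s:e] for s, e in spans]
    ['GGG', 'GGGG']
    """
    g_run_lengths = list(g_run_lengths)
    if any(l < 3 for l in g_run_lengths):
        raise SpliceCorError("planted G-runs must have length >= 3")
    k = len(g_run_lengths)
    free = length - sum(g_run_lengths) - max(0, k - 1)
    if free < 0:
        raise SpliceCorError(
            f"cannot place runs totalling {sum(g_run_lengths)} nt with spacers in {length} nt"
        )
    rng = np.random.default_rng(seed)
    # distribute the free non-G length over k+1 gaps; internal gaps get +1 spacer
    gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
    gaps[1:k] += 1 if k > 1 else 0
    background = rng.choice(list("ACT"), size=length - sum(g_run_lengths))

    seq_parts, spans = [], []
    bg_pos = 0
    cursor = 0
    for i, run_len in enumerate(g_run_lengths):
        gap = int(gaps[i])
        seq_parts.append("".join(background[bg_pos:bg_pos + gap]))
        bg_pos += gap
        cursor += gap
        spans.append((cursor, cursor + run_len))
        seq_parts.append("G" * run_len)
        cursor += run_len
    seq_parts.append("".join(background[bg_pos:]))
    return "".join(seq_parts), spans
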