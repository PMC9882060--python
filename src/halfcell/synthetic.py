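"""Synthetic paired anterior/posterior half-cell TPM profiles with known
regionalization and knockdown perturbations.

The generator emulates the half-cell experimental design: single cells are
bisected along the anterior-posterior axis and each half is sequenced, giving
a paired A/P TPM profile per cell. A fraction of genes carries a true
abundance skew ``s`` in (-1, 1): the anterior half receives a fraction
``(1+s)/2`` of the gene's abundance and the posterior ``(1-s)/2``. Under a
knockdown, each regionalized gene either flips sign (anterior-enriched
becomes posterior-enriched), loses its skew entirely, or retains it.

Two noise sources mimic the experiment. A per-pair *bisection error* — the
cut never lands exactly mid-cell — shifts the effective skew of every gene
in that pair by one shared offset. Independent multiplicative log-normal
noise models sequencing/capture variability per gene and half. Each half
profile is finally rescaled to sum to 1e6 (the TPM convention), exactly as a
quantifier would normalize it.

The true skew ``s`` is a parameter of raw abundance, not of the pipeline's
estimated skew (which is computed on adjusted log values and is numerically
smaller); only sign and rank-order recovery are meaningful comparisons.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import io as hio

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_truth",
    "generate_pair",
    "generate_experiment",
    "write_experiment",
]

TPM_TOTAL = 1_000_000.0
#: truncation bound for true skew magnitudes
MAX_TRUE_SKEW = 0.95

KD_CLASSES = ("flipped", "lost", "retained", "null")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated half-cell experiment.

    Defaults describe the reference scenario used throughout the package:
    2000 genes, 15% regionalized with true skews around 0.4, six control and
    six knockdown pairs, multiplicative noise sd 0.2 (log scale), bisection
    error sd 0.05, and knockdown fractions 0.4 flipped / 0.4 lost / 0.2
    retained among regionalized genes. Baselines are log-normal
    (``ln``-scale mean 3, sd 1.5), a realistic heavy-tailed expression
    profile.
    """

    n_genes: int = 2000
    n_pairs_control: int = 6
    n_pairs_kd: int = 6
    frac_regionalized: float = 0.15
    skew_effect_mean: float = 0.4
    skew_effect_sd: float = 0.1
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    noise_sd: float = 0.2
    bisection_error_sd: float = 0.05
    kd_frac_flip: float = 0.4
    kd_frac_loss: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pairs_control", "n_pairs_kd"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        for name in ("frac_regionalized", "kd_frac_flip", "kd_frac_loss"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.kd_frac_flip + self.kd_frac_loss > 1.0 + 1e-12:
            raise ValueError("kd_frac_flip + kd_frac_loss must not exceed 1")
        for name in ("skew_effect_sd", "baseline_log_sd", "noise_sd",
                     "bisection_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Per-gene true state: control skew, knockdown class, baseline abundance."""

    table: pd.DataFrame  # index gene_id; columns true_skew_control, kd_class, baseline

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_in_class(self, kd_class: str) -> pd.Index:
        return self.table.index[self.table["kd_class"] == kd_class]


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"gene_{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")


def generate_truth(config: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the per-gene ground truth for one experiment.

    Exactly ``round(frac_regionalized * n_genes)`` genes get a nonzero true
    skew, drawn as a random sign times |Normal(skew_effect_mean,
    skew_effect_sd)| truncated to (0, 0.95); knockdown classes are assigned
    among them by the configured fractions (remainder retained). Baselines
    are log-normal. Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = _gene_ids(n)
    n_reg = round(config.frac_regionalized * n)
    skew = np.zeros(n)
    kd_class = np.full(n, "null", dtype=object)
    reg_idx = rng.choice(n, size=n_reg, replace=False)
    magnitudes = np.abs(rng.normal(config.skew_effect_mean, config.skew_effect_sd,
                                   size=n_reg))
    for _ in range(100):
        bad = (magnitudes >= MAX_TRUE_SKEW) | (magnitudes <= 0)
        if not bad.any():
            break
        magnitudes[bad] = np.abs(
            rng.normal(config.skew_effect_mean, config.skew_effect_sd,
                       size=int(bad.sum()))
        )
    np.clip(magnitudes, 1e-6, MAX_TRUE_SKEW - 1e-9, out=magnitudes)
    signs = rng.choice([-1.0, 1.0], size=n_reg)
    skew[reg_idx] = signs * magnitudes
    n_flip = round(config.kd_frac_flip * n_reg)
    n_loss = min(round(config.kd_frac_loss * n_reg), n_reg - n_flip)
    shuffled = rng.permutation(reg_idx)
    kd_class[shuffled[:n_flip]] = "flipped"
    kd_class[shuffled[n_flip:n_flip + n_loss]] = "lost"
    kd_class[shuffled[n_flip + n_loss:]] = "retained"
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    table = pd.DataFrame(
        {"true_skew_control": skew, "kd_class": kd_class, "baseline": baseline},
        index=genes,
    )
    return GroundTruth(table=table)


def generate_pair(
    truth: GroundTruth,
    condition: str,
    config: SimConfig,
    rng: np.random.Generator,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (anterior, posterior) TPM vector pair.

    ``condition`` is ``"control"`` or ``"kd"``. The effective skew is
    ``clip(s + delta, -1, 1)`` where ``s`` is the condition-specific true skew
    (negated for flipped genes and zeroed for lost genes under kd) and
    ``delta ~ Normal(0, bisection_error_sd)`` is one shared per-pair offset.
    Raw abundances ``baseline * (1 +/- s')/2 * exp(eps)`` with i.i.d.
    ``eps ~ Normal(0, noise_sd)`` are rescaled so each half sums to 1e6
    (skipped when ``normalize=False``, exposing the raw vectors).
    """
    if condition not in ("control", "kd"):
        raise ValueError("condition must be 'control' or 'kd'")
    table = truth.table
    s = table["true_skew_control"].to_numpy(dtype=float).copy()
    if condition == "kd":
        kd_class = table["kd_class"].to_numpy()
        s[kd_class == "flipped"] *= -1.0
        s[kd_class == "lost"] = 0.0
    delta = rng.normal(0.0, config.bisection_error_sd)
    s_eff = np.clip(s + delta, -1.0, 1.0)
    baseline = table["baseline"].to_numpy(dtype=float)
    eps_a = rng.normal(0.0, config.noise_sd, size=len(s))
    eps_p = rng.normal(0.0, config.noise_sd, size=len(s))
    anterior = baseline * (1.0 + s_eff) / 2.0 * np.exp(eps_a)
    posterior = baseline * (1.0 - s_eff) / 2.0 * np.exp(eps_p)
    if normalize:
        anterior = anterior * (TPM_TOTAL / anterior.sum())
        posterior = posterior * (TPM_TOTAL / posterior.sum())
    return anterior, posterior


def generate_experiment(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a full paired half-cell experiment.

    Returns ``(tpm_matrix, sample_sheet, truth)``: a genes x half-samples TPM
    matrix with ``2 * (n_pairs_control + n_pairs_kd)`` columns, a sample
    sheet (sample_id, pair_id, half, condition, batch) that passes pairing
    validation by construction, and the ground truth. One pseudo-random
    stream, seeded from ``config.seed``, drives truth and all pairs, so the
    output is byte-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    truth = generate_truth(config, rng=rng)
    columns: dict[str, np.ndarray] = {}
    rows = []
    plan = [("control", i) for i in range(config.n_pairs_control)] + [
        ("kd", i) for i in range(config.n_pairs_kd)
    ]
    for condition, i in plan:
        pair_id = f"{condition}_p{i + 1:02d}"
        anterior, posterior = generate_pair(truth, condition, config, rng)
        for half, vec in (("A", anterior), ("P", posterior)):
            sample_id = f"{pair_id}_{half}"
            columns[sample_id] = vec
            rows.append(
                {"sample_id": sample_id, "pair_id": pair_id, "half": half,
                 "condition": condition, "batch": "sim"}
            )
    matrix = pd.DataFrame(columns, index=truth.gene_ids)
    sheet = pd.DataFrame(rows, columns=list(hio.SHEET_COLUMNS))
    return matrix, sheet, truth


def write_experiment(
    out_dir: str | os.PathLike,
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Write pipeline-ready fixtures: one kallisto-dialect abundance.tsv per
    half-sample, the sample sheet, and the ground-truth table."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for sample_id in matrix.columns:
        hio.write_kallisto_abundance(
            os.path.join(out_dir, f"{sample_id}.abundance.tsv"), matrix[sample_id]
        )
    sheet.to_csv(os.path.join(out_dir, "sample_sheet.tsv"), sep="\t", index=False)
    truth.table.to_csv(os.path.join(out_dir, "ground_truth.tsv"), sep="\t")


def config_dict(config: SimConfig) -> dict:
    """Plain-dict form of a config, for manifests."""
    return asdict(config)
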