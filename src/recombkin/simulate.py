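"""Synthetic selection experiments: ground-truth libraries, in vitro
selection, FASTQ read sampling, and qPCR readouts.

The generator emulates the in vitro selection that produced the real data:
a saturation-mutagenesis library (default uniform naïve composition) reacts
with recombinase for a short time; each variant flips a first-order fraction
``F_s = 1 - exp(-rate_scale * k_s * t)`` of its molecules, where its
ground-truth rate constant ``k_s`` is the product of per-position weight
scores; the flipped pool is then sequenced to a fixed depth with independent
per-base substitution errors. Every stage is seeded and deterministic, so the
whole analysis pipeline can be exercised and parameter recovery verified
without any external data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from functools import cached_property
from typing import Optional

import numpy as np

from .design import (
    BASE_ASCII,
    LibraryDesign,
    codes_to_strings,
    library_codes,
)
from .model import WeightMatrix
from .rates import StandardCurve, flipped_fractions

__all__ = [
    "GroundTruth",
    "SelectionConfig",
    "SelectionResult",
    "generate_ground_truth",
    "simulate_selection",
    "sample_reads",
    "simulate_cq",
]


@dataclass
class GroundTruth:
    """A library with known per-position weight scores and naïve composition."""

    design: LibraryDesign
    true_weights: WeightMatrix
    naive_abundances: np.ndarray  # over the lexicographic enumeration order
    seed: int

    def __post_init__(self):
        ab = np.asarray(self.naive_abundances, dtype=float)
        if ab.shape != (self.design.library_size,):
            raise ValueError("one naïve abundance required per library variant")
        if (ab < 0).any():
            raise ValueError("naïve abundances must be non-negative")
        s = ab.sum()
        if not np.isclose(s, 1.0, rtol=0, atol=1e-9):
            raise ValueError("naïve abundances must sum to 1")
        self.naive_abundances = ab


@dataclass(frozen=True)
class SelectionConfig:
    """Conditions of a simulated selection round.

    ``rate_scale`` is a dimensionless multiplier standing in for enzyme
    concentration; the default (5e-5 with the 5-min reaction) puts the pool's
    total flipped fraction around 0.002%, i.e. the deep initial-rate regime
    of a low-enzyme selection. ``saturation_b > 0`` optionally compresses
    rate differences the way a high enzyme concentration does.
    """

    reaction_time: float = 5.0  # minutes
    rate_scale: float = 5e-5
    read_depth: int = 500_000
    base_error_rate: float = 0.001
    saturation_b: float = 0.0
    seed: int = 42

    def __post_init__(self):
        if min(self.reaction_time, self.rate_scale, self.read_depth) < 0:
            raise ValueError("reaction_time, rate_scale, read_depth must be >= 0")
        if not 0.0 <= self.base_error_rate < 0.25:
            raise ValueError("base_error_rate must lie in [0, 0.25)")


@dataclass
class SelectionResult:
    """Per-variant outcome of a simulated selection.

    ``flipped_share`` (composition of the flipped pool, summing to 1) is None
    when no flipping occurred (rate_scale = 0) — the pool is undefined rather
    than silently zero.
    """

    design: LibraryDesign
    codes: np.ndarray  # (N, P) uint8 base codes, lexicographic order
    k_true: np.ndarray
    flipped_fraction: np.ndarray
    naive: np.ndarray
    flipped_share: Optional[np.ndarray]
    total_flipped_fraction: float

    @cached_property
    def variants(self) -> np.ndarray:
        return codes_to_strings(self.codes)

    def to_frame(self, top: Optional[int] = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "variant": self.variants,
                "k_true": self.k_true,
                "flipped_fraction": self.flipped_fraction,
                "naive_abundance": self.naive,
                "flipped_share": (
                    self.flipped_share
                    if self.flipped_share is not None
                    else np.nan
                ),
            }
        )
        if top is not None:
            df = df.nlargest(top, "flipped_share")
        return df


def generate_ground_truth(
    design: LibraryDesign,
    seed: int = 42,
    weight_low: float = 0.01,
    weight_high: float = 4.0,
    naive: str = "uniform",
    dirichlet_alpha: float = 50.0,
) -> GroundTruth:
    """Draw a ground-truth weight matrix and naïve library composition.

    Non-WT weights are log-uniform on ``[weight_low, weight_high]`` (the
    observed weight range spans ~0.01 to 4); WT weights are pinned to 1 by
    the gauge. ``naive="dirichlet"`` perturbs the default uniform naïve pool
    for robustness studies (concentration ``dirichlet_alpha`` per variant).
    """
    if not 0 < weight_low <= 1 <= weight_high:
        raise ValueError("require 0 < weight_low <= 1 <= weight_high")
    rng = np.random.default_rng(seed)
    p = design.n_positions
    log10 = np.zeros((p, 4))
    log10[:, 1:] = rng.uniform(np.log10(weight_low), np.log10(weight_high), size=(p, 3))
    weights = WeightMatrix(design=design, log10=log10)

    n = design.library_size
    if naive == "uniform":
        ab = np.full(n, 1.0 / n)
    elif naive == "dirichlet":
        ab = rng.dirichlet(np.full(n, dirichlet_alpha))
    else:
        raise ValueError(f"unknown naïve composition {naive!r}")
    return GroundTruth(design=design, true_weights=weights, naive_abundances=ab, seed=seed)


def true_kflips(truth: GroundTruth) -> np.ndarray:
    """Ground-truth k_flip of every library variant (product of weights)."""
    codes = library_codes(truth.design)
    log_acgt = truth.true_weights.log10_acgt
    logk = np.zeros(codes.shape[0])
    for i in range(codes.shape[1]):
        logk += log_acgt[i, codes[:, i]]
    return 10.0 ** logk


def simulate_selection(truth: GroundTruth, config: SelectionConfig) -> SelectionResult:
    """First-order selection of the whole library.

    Each variant flips ``F_s = 1 - exp(-rate_scale * k_s * t)`` of its
    molecules; the flipped pool composition is ``naive_s * F_s`` normalized
    to 1.
    """
    codes = library_codes(truth.design)
    k = true_kflips(truth)
    F = flipped_fractions(k, config.rate_scale, config.reaction_time, config.saturation_b)
    pool = truth.naive_abundances * F
    total = float(pool.sum())
    share = pool / total if total > 0 else None
    return SelectionResult(
        design=truth.design,
        codes=codes,
        k_true=k,
        flipped_fraction=F,
        naive=truth.naive_abundances,
        flipped_share=share,
        total_flipped_fraction=float((truth.naive_abundances * F).sum()),
    )


def _write_fastq(path, read_codes: np.ndarray, prefix: str) -> None:
    n, L = read_codes.shape
    qual = "I" * L  # constant Q40; qualities are not used downstream
    seqs = BASE_ASCII[read_codes].view(f"S{L}").ravel()
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i in range(n):
            fh.write(f"@{prefix}_{i}\n{seqs[i].decode('ascii')}\n+\n{qual}\n")


def _sample_pool_reads(
    composition: np.ndarray,
    codes: np.ndarray,
    design: LibraryDesign,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial read sampling with per-base substitution errors.

    Returns (per-variant counts, (depth, L) read code matrix)."""
    counts = rng.multinomial(depth, composition)
    nz = np.flatnonzero(counts)
    var_rows = np.repeat(codes[nz], counts[nz], axis=0)

    L = design.halfsite_length
    ref = np.frombuffer(design.reference_halfsite.encode("ascii"), dtype=np.uint8)
    from .design import BASE_CODE_LUT

    reads = np.tile(BASE_CODE_LUT[ref], (depth, 1))
    var_idx = np.array([p - 1 for p in design.variable_positions], dtype=np.intp)
    reads[:, var_idx] = var_rows

    if error_rate > 0:
        mask = rng.random(reads.shape) < error_rate
        n_err = int(mask.sum())
        # substitution-only, uniform over the 3 alternative bases
        reads[mask] = (reads[mask] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
    return counts, reads


def sample_reads(
    result: SelectionResult,
    config: SelectionConfig,
    out_selected,
    out_naive=None,
    seed: Optional[int] = None,
) -> dict:
    """Sample sequencing reads from the flipped pool (and optionally the
    naïve library) into FASTQ files (Phred+33, gzip by ``.gz`` suffix).

    Each read is the reference half-site with the drawn variant's bases
    substituted, then independent substitution errors applied at
    ``config.base_error_rate``. Returns the per-variant read counts.
    """
    if result.flipped_share is None:
        raise ValueError("no flipped pool to sample (rate_scale was 0)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sel_counts, sel_reads = _sample_pool_reads(
        result.flipped_share, result.codes, result.design,
        config.read_depth, config.base_error_rate, rng,
    )
    _write_fastq(out_selected, sel_reads, "sel")
    out = {"selected": out_selected, "selected_counts": sel_counts}
    if out_naive is not None:
        naive_counts, naive_reads = _sample_pool_reads(
            result.naive, result.codes, result.design,
            config.read_depth, config.base_error_rate, rng,
        )
        _write_fastq(out_naive, naive_reads, "naive")
        out.update({"naive": out_naive, "naive_counts": naive_counts})
    return out


def simulate_cq(
    copies: float,
    curve: StandardCurve,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """qPCR quantification cycle for a given template copy number."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    cq = curve.slope * np.log10(copies) + curve.intercept
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        cq += rng.normal(0.0, noise_sd)
    return float(cq)
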