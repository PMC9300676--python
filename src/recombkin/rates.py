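"""qPCR quantification and frequency -> relative rate-constant conversion.

The inversion of a single attP-L variant is treated as a first-order reaction
with rate constant ``k_flip``: after reaction time *t* a fraction
``F = 1 - exp(-k_flip * t)`` of its molecules is flipped. Under dilute
(initial-rate) selection conditions, a variant's share of the flipped pool —
and hence its NGS read frequency — is proportional to its flipped DNA, so
relative rate constants follow from read frequencies. Rates are reported
relative to wild type (WT ≡ 1), the same gauge used for the weight-score
model.

Flipped DNA is quantified by qPCR against a standard curve
``Cq = slope * log10(copies) + intercept``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import FrequencyTable
from .design import AttVariant

__all__ = [
    "StandardCurve",
    "RateTable",
    "fit_standard_curve",
    "cq_to_copies",
    "flipped_percentage",
    "flipped_fractions",
    "freq_to_kflip",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear qPCR calibration: Cq vs log10(template copies)."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    linear_range_low: float = 1e3  # copies; quantification below this is flagged

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


#: the calibration reported for the flipped-product assay
PAPER_STANDARD_CURVE = StandardCurve(
    slope=-3.378, intercept=40.169, r_squared=0.998, linear_range_low=1e3
)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Cq on log10(copies).

    Requires at least 3 points spanning at least two decades of copy number.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (copies, Cq) points")
    copies, cq = pts[:, 0], pts[:, 1]
    if (copies <= 0).any():
        raise ValueError("copy numbers must be positive")
    x = np.log10(copies)
    if np.ptp(x) < 2.0:
        raise ValueError("standard-curve points must span >= 2 decades")
    res = stats.linregress(x, cq)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        linear_range_low=float(copies.min()),
    )


def cq_to_copies(curve: StandardCurve, cq: float) -> float:
    """Invert the standard curve: ``copies = 10**((cq - intercept)/slope)``.

    Emits a warning when the result falls below the curve's linear range.
    """
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    if copies < curve.linear_range_low:
        import warnings

        warnings.warn(
            f"{copies:.3g} copies is below the linear range "
            f"(~{curve.linear_range_low:.0g}); quantification unreliable"
        )
    return copies


def flipped_percentage(flipped_copies: float, total_copies: float) -> float:
    """Percent of the DNA pool that underwent inversion."""
    if total_copies <= 0:
        raise ValueError("total copies must be positive")
    if flipped_copies < 0 or flipped_copies > total_copies:
        raise ValueError("flipped copies must lie in [0, total]")
    return 100.0 * flipped_copies / total_copies


def flipped_fractions(
    k: np.ndarray | float,
    rate_scale: float,
    reaction_time: float,
    saturation_b: float = 0.0,
) -> np.ndarray:
    """First-order flipped fraction ``F = 1 - exp(-rate_scale * k * t)``.

    ``saturation_b > 0`` applies the optional enzyme-saturation transform
    ``k -> k / (1 + b*k)``, which qualitatively compresses rate differences at
    high enzyme concentration. Uses ``expm1`` so the deep initial-rate regime
    (F ~ 1e-9) stays accurate.
    """
    k = np.asarray(k, dtype=float)
    eff = rate_scale * k / (1.0 + saturation_b * k)
    return -np.expm1(-eff * reaction_time)


def _as_variant_str(wt) -> str:
    return wt.bases if isinstance(wt, AttVariant) else str(wt)


@dataclass
class RateTable:
    """Per-variant relative k_flip (WT ≡ 1) with log10 values.

    ``provenance`` records how the rates were obtained: conversion mode,
    reaction time, pool flipped fraction (exact mode), naïve correction, and
    the log base (10).
    """

    df: pd.DataFrame  # index variant, columns k_flip, log10_k_flip
    wt: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.df["k_flip"] <= 0).any():
            raise ValueError("k_flip must be positive")
        if self.wt in self.df.index and not np.isclose(
            self.df.at[self.wt, "k_flip"], 1.0, rtol=0, atol=0
        ):
            raise ValueError("WT entry must be exactly 1")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant) -> bool:
        return _as_variant_str(variant) in self.df.index

    def k_flip(self, variant) -> float:
        return float(self.df.at[_as_variant_str(variant), "k_flip"])

    def subset(self, variants: Sequence[str]) -> "RateTable":
        return RateTable(
            df=self.df.loc[list(variants)].copy(), wt=self.wt,
            provenance=dict(self.provenance),
        )

    def to_tsv(self, path) -> None:
        out = self.df.reset_index()
        out.columns = ["variant", "k_flip", "log10_k_flip"]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, wt: str) -> "RateTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant": str}).set_index("variant")
        return cls(df=df[["k_flip", "log10_k_flip"]], wt=str(wt))

    @classmethod
    def from_kflips(cls, kflips: dict | pd.Series, wt: str, **provenance) -> "RateTable":
        s = pd.Series(kflips, dtype=float)
        df = pd.DataFrame({"k_flip": s, "log10_k_flip": np.log10(s)})
        df.index.name = "variant"
        return cls(df=df, wt=str(wt), provenance=provenance)


def freq_to_kflip(
    table: FrequencyTable,
    wt: AttVariant | str,
    mode: str = "linear",
    reaction_time: float = 5.0,
    pool_flipped_fraction: Optional[float] = None,
    naive: Optional[FrequencyTable] = None,
) -> RateTable:
    """Convert flipped-pool read frequencies into relative rate constants.

    linear mode (default)
        ``k_s = (f_s / naive_s) / (f_WT / naive_WT)`` — exact in the
        initial-rate limit where the flipped fraction of every variant is
        proportional to its k_flip. Naïve ratios are taken as 1 when no naïve
        table is supplied (uniform library).

    exact mode
        Requires the pool's overall flipped fraction (from qPCR). Each
        variant's own flipped fraction is reconstructed as
        ``F_s = pool_flipped_fraction * f_s / naive_s`` with naïve abundances
        defaulting to the uniform ``4**-P``, and
        ``k_s = log(1 - F_s) / log(1 - F_WT)``.

    The WT entry is exactly 1 in both modes. The provenance of an exact-mode
    table additionally records the absolute WT rate in min^-1.
    """
    wt_str = _as_variant_str(wt)
    if wt_str not in table:
        raise ValueError("WT variant absent from the frequency table")
    if table.count(wt_str) < 1:
        raise ValueError("WT variant has zero count")

    f = table.df["frequency"]
    variants = f.index

    if naive is not None:
        missing = variants.difference(naive.df.index)
        if len(missing):
            import warnings

            warnings.warn(
                f"{len(missing)} variants missing from the naïve table were dropped"
            )
            variants = variants.difference(missing, sort=False)
            if wt_str not in variants:
                raise ValueError("WT variant missing from the naïve table")
            f = f.loc[variants]
        naive_ab = naive.df["frequency"].loc[variants]
    else:
        p = len(wt_str)
        naive_ab = pd.Series(4.0 ** -p, index=variants)

    provenance = {
        "mode": mode,
        "reaction_time_min": reaction_time,
        "naive_corrected": naive is not None,
        "log_base": 10,
    }

    if mode == "linear":
        ratio = (f / naive_ab) / (f[wt_str] / naive_ab[wt_str])
        k = ratio
    elif mode == "exact":
        if pool_flipped_fraction is None:
            raise ValueError("exact mode requires pool_flipped_fraction")
        F = pool_flipped_fraction * f / naive_ab
        if (F >= 1.0).any():
            raise ValueError(
                "reconstructed per-variant flipped fraction >= 1; "
                "inputs inconsistent with the assumed naïve abundances"
            )
        log_surv = np.log1p(-F)
        k = log_surv / log_surv[wt_str]
        provenance["pool_flipped_fraction"] = pool_flipped_fraction
        provenance["absolute_wt_rate_per_min"] = float(
            -log_surv[wt_str] / reaction_time
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    k = pd.Series(np.asarray(k, dtype=float), index=variants)
    k[wt_str] = 1.0  # gauge, exact
    df = pd.DataFrame({"k_flip": k, "log10_k_flip": np.log10(k)})
    df.index.name = "variant"
    return RateTable(df=df, wt=wt_str, provenance=provenance)
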