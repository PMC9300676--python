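"""Multiplicative position-weight model of recombination rate constants.

The model assumes each nucleotide of the attP-L half-site contributes
independently and multiplicatively to the inversion rate constant:

    k_flip = prod_i W[i, b(i)]          (b(i) = base carried at position i)

so log10(k_flip) is linear in the log-weights. The scale indeterminacy is
removed by the wild-type gauge W[i, WT base] = 1, imposed structurally: the
design matrix is the one-hot encoding with the WT columns *dropped* and no
intercept, which makes the WT prediction k = 1 exact rather than approximate.

:class:`WeightScoreRegressor` is a scikit-learn estimator (``fit`` /
``predict`` on log10 rate constants); :class:`OneHotVariantEncoder` is the
matching transformer. Module-level functions (:func:`fit_weights`,
:func:`predict_kflip`, :func:`train_val_split`, :func:`prediction_errors`,
:func:`sensitivity_curve`, :func:`classify_weights`) mirror the pipeline's
operations as thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .design import BASES, AttVariant, LibraryDesign, validate_variant
from .rates import RateTable, flipped_fractions

__all__ = [
    "WeightMatrix",
    "FitResult",
    "PredictionErrors",
    "SensitivityCurve",
    "OneHotVariantEncoder",
    "WeightScoreRegressor",
    "UnidentifiedWeightError",
    "fit_weights",
    "predict_kflip",
    "train_val_split",
    "prediction_errors",
    "sensitivity_curve",
    "classify_weights",
    "simulate_frequency_profile",
]


class UnidentifiedWeightError(ValueError):
    """Prediction requested for a position-base weight never seen in training."""


@dataclass
class WeightMatrix:
    """Weight scores W_ij with the WT gauge (column 1 of each position ≡ 1).

    ``log10`` is a (P, 4) array in per-position column order — column 0 is the
    WT base, columns 1–3 the non-WT bases alphabetically (the design records
    the convention). NaN marks position-base combinations never observed in
    training ("unidentified"); these raise at prediction time rather than
    silently acting as 1.
    """

    design: LibraryDesign
    log10: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.log10, dtype=float)
        if arr.shape != (self.design.n_positions, 4):
            raise ValueError("log10 weight array must be (P, 4)")
        if not np.all(arr[:, 0] == 0.0):
            raise ValueError("WT gauge violated: column 1 must be exactly 0 in log10")
        object.__setattr__(self, "log10", arr)

    # -- lookups ---------------------------------------------------------

    def _col(self, position: int, base: str) -> tuple[int, int]:
        i = self.design.position_index(position)
        cols = self.design.base_columns()[i]
        return i, cols.index(base.upper())

    def log10_weight(self, position: int, base: str) -> float:
        i, j = self._col(position, base)
        return float(self.log10[i, j])

    def weight(self, position: int, base: str) -> float:
        return float(10.0 ** self.log10_weight(position, base))

    def identified(self, position: int, base: str) -> bool:
        i, j = self._col(position, base)
        return bool(np.isfinite(self.log10[i, j]))

    @property
    def log10_acgt(self) -> np.ndarray:
        """(P, 4) log10 weights reindexed to fixed A,C,G,T column order."""
        out = np.empty_like(self.log10)
        for i, cols in enumerate(self.design.base_columns()):
            for j, b in enumerate(cols):
                out[i, BASES.index(b)] = self.log10[i, j]
        return out

    def variant_log10(self, variant: AttVariant | str) -> float:
        """Sum of log10 weights along a variant (log of the product model)."""
        bases = variant.bases if isinstance(variant, AttVariant) else str(variant)
        validate_variant(AttVariant(bases), self.design)
        acgt = self.log10_acgt
        total = 0.0
        for i, b in enumerate(bases):
            v = acgt[i, BASES.index(b)]
            if not np.isfinite(v):
                pos = self.design.variable_positions[i]
                raise UnidentifiedWeightError(
                    f"weight for base {b} at position {pos} was never observed in training"
                )
            total += v
        return total

    # -- tables ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        cats = classify_weights(self)
        for i, pos in enumerate(self.design.variable_positions):
            for j, b in enumerate(self.design.base_columns()[i]):
                lw = self.log10[i, j]
                rows.append(
                    {
                        "position": pos,
                        "base": b,
                        "is_wt": j == 0,
                        "W": 10.0 ** lw if np.isfinite(lw) else np.nan,
                        "log10_W": lw,
                        "category": cats[(pos, b)],
                        "identified": bool(np.isfinite(lw)),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, design: LibraryDesign) -> "WeightMatrix":
        arr = np.full((design.n_positions, 4), np.nan)
        arr[:, 0] = 0.0
        cols = design.base_columns()
        for _, row in df.iterrows():
            i = design.position_index(int(row["position"]))
            j = cols[i].index(str(row["base"]).upper())
            if j > 0 and np.isfinite(row["log10_W"]):
                arr[i, j] = float(row["log10_W"])
        return cls(design=design, log10=arr)

    @classmethod
    def from_tsv(cls, path, design: LibraryDesign) -> "WeightMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"), design)


def classify_weights(weights: WeightMatrix) -> dict[tuple[int, str], str]:
    """Classify every position-base weight by its effect on recombination.

    ``enhancing`` (W > 1), ``wt-like`` (W = 1), ``moderate-loss``
    (0.1 < W < 1), ``disrupting`` (W <= 0.1, boundary inclusive), or
    ``unidentified``.
    """
    out: dict[tuple[int, str], str] = {}
    for i, pos in enumerate(weights.design.variable_positions):
        for j, b in enumerate(weights.design.base_columns()[i]):
            lw = weights.log10[i, j]
            if not np.isfinite(lw):
                cat = "unidentified"
            elif lw > 0:
                cat = "enhancing"
            elif lw == 0:
                cat = "wt-like"
            elif lw > -1:
                cat = "moderate-loss"
            else:
                cat = "disrupting"
            out[(pos, b)] = cat
    return out


# ---------------------------------------------------------------------------
# scikit-learn surface
# ---------------------------------------------------------------------------


class OneHotVariantEncoder(TransformerMixin, BaseEstimator):
    """Encode attP-L variants as a reduced one-hot design matrix.

    With ``drop_wt=True`` (default) the WT-base column of every position is
    dropped, yielding an (n, 3P) matrix on which an intercept-free linear fit
    of log10(k_flip) realizes the WT gauge exactly.
    """

    def __init__(self, design: Optional[LibraryDesign] = None, drop_wt: bool = True):
        self.design = design
        self.drop_wt = drop_wt

    def fit(self, X, y=None):
        if self.design is None:
            raise ValueError("a LibraryDesign is required")
        self.n_features_in_ = 1
        p = self.design.n_positions
        self.feature_names_out_ = np.array(
            [
                f"{cols[0]}{pos}{b}"
                for pos, cols in zip(self.design.variable_positions, self.design.base_columns())
                for b in (cols[1:] if self.drop_wt else cols)
            ]
        )
        self.n_output_features_ = (3 if self.drop_wt else 4) * p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "feature_names_out_")
        design = self.design
        p = design.n_positions
        cols = design.base_columns()
        width = 3 if self.drop_wt else 4
        out = np.zeros((len(X), width * p), dtype=float)
        for r, v in enumerate(X):
            bases = v.bases if isinstance(v, AttVariant) else str(v)
            validate_variant(AttVariant(bases), design)
            for i, b in enumerate(bases):
                j = cols[i].index(b)
                if self.drop_wt:
                    if j > 0:
                        out[r, i * 3 + (j - 1)] = 1.0
                else:
                    out[r, i * 4 + j] = 1.0
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return self.feature_names_out_


class WeightScoreRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of log10(k_flip) on one-hot attP-L variants.

    Parameters
    ----------
    design : LibraryDesign
        The mutagenesis scheme; defines positions and the WT gauge.
    alpha : float, default 0.0
        Optional ridge penalty on the log-weights. Plain least squares (the
        default) matches the original fitting procedure; the penalty exists
        only to stabilize deliberately under-determined fits in the
        training-set-size sweep.

    ``fit(X, y)`` accepts variant base strings (or :class:`AttVariant`) and
    experimental log10(k_flip) values. Position-base combinations never
    observed in training are left *unidentified* (NaN coefficients) and raise
    :class:`UnidentifiedWeightError` at prediction time.

    Attributes (after fit): ``coef_`` (3P log10-weights, NaN = unidentified),
    ``weight_matrix_``, ``residuals_``, ``rmse_``, ``mae_``,
    ``rank_deficient_``, ``feature_names_in_``.
    """

    def __init__(self, design: Optional[LibraryDesign] = None, alpha: float = 0.0):
        self.design = design
        self.alpha = alpha

    def _encode(self, X) -> np.ndarray:
        X = list(X) if not isinstance(X, np.ndarray) else X
        if isinstance(X, np.ndarray) and X.ndim == 2 and np.issubdtype(X.dtype, np.number):
            return np.asarray(X, dtype=float)
        enc = OneHotVariantEncoder(design=self.design).fit(None)
        self._feature_names = enc.feature_names_out_
        return enc.transform(X)

    def fit(self, X, y, sample_weight=None):
        if self.design is None:
            raise ValueError("a LibraryDesign is required")
        A = self._encode(X)
        y = np.asarray(y, dtype=float)
        if A.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if A.shape[0] < 1:
            raise ValueError("at least one training sequence is required")
        Aw, yw = A, y
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float))
            Aw, yw = A * w[:, None], y * w

        observed = A.any(axis=0)
        coef = np.full(A.shape[1], np.nan)
        if observed.any():
            Ao = Aw[:, observed]
            if self.alpha > 0:
                g = Ao.T @ Ao + self.alpha * np.eye(Ao.shape[1])
                coef_o = np.linalg.solve(g, Ao.T @ yw)
                rank = Ao.shape[1]
            else:
                coef_o, _, rank, _ = np.linalg.lstsq(Ao, yw, rcond=None)
            coef[observed] = coef_o
            self.rank_deficient_ = rank < Ao.shape[1]
            if self.rank_deficient_ and self.alpha == 0:
                warnings.warn(
                    f"design matrix rank {rank} < {Ao.shape[1]} observed weight "
                    "columns; the fit is under-determined (minimum-norm solution)"
                )
        else:
            self.rank_deficient_ = False

        self.coef_ = coef
        self.observed_mask_ = observed
        self.n_features_in_ = A.shape[1]
        if hasattr(self, "_feature_names"):
            self.feature_names_in_ = self._feature_names
        self.weight_matrix_ = self._to_weight_matrix(coef)
        fitted = A @ np.where(observed, np.nan_to_num(coef), 0.0)
        self.residuals_ = fitted - y  # predicted minus experimental, log10
        self.rmse_ = float(np.sqrt(np.mean(self.residuals_**2)))
        self.mae_ = float(np.mean(np.abs(self.residuals_)))
        return self

    def _to_weight_matrix(self, coef: np.ndarray) -> WeightMatrix:
        p = self.design.n_positions
        arr = np.full((p, 4), np.nan)
        arr[:, 0] = 0.0  # WT gauge
        arr[:, 1:] = coef.reshape(p, 3)
        return WeightMatrix(design=self.design, log10=arr)

    def predict(self, X) -> np.ndarray:
        """Predicted log10(k_flip). Raises if X touches unidentified weights."""
        check_is_fitted(self, "coef_")
        A = self._encode(X)
        bad = A[:, ~self.observed_mask_].any(axis=1)
        if bad.any():
            raise UnidentifiedWeightError(
                f"{int(bad.sum())} variant(s) carry position-base combinations "
                "never observed in training"
            )
        return A @ np.nan_to_num(self.coef_)

    def predict_kflip(self, X) -> np.ndarray:
        return 10.0 ** self.predict(X)


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a weight-score fit on a rate table."""

    weights: WeightMatrix
    residuals: pd.Series  # predicted - experimental log10(k_flip), per sequence
    rmse: float
    mae: float
    n_train: int
    estimator: WeightScoreRegressor = field(repr=False, default=None)


def fit_weights(
    rates: RateTable,
    design: LibraryDesign,
    alpha: float = 0.0,
    count_weighted: bool = False,
    counts: Optional[pd.Series] = None,
) -> FitResult:
    """Fit the weight-score model to a table of relative rate constants.

    ``count_weighted`` weights each sequence's squared residual by its read
    count (requires ``counts``); the default is unweighted, matching plain
    least squares.
    """
    variants = rates.df.index.to_numpy(dtype=str)
    y = rates.df["log10_k_flip"].to_numpy(dtype=float)
    sw = None
    if count_weighted:
        if counts is None:
            raise ValueError("count_weighted=True requires counts")
        sw = counts.loc[rates.df.index].to_numpy(dtype=float)
    est = WeightScoreRegressor(design=design, alpha=alpha).fit(variants, y, sample_weight=sw)
    return FitResult(
        weights=est.weight_matrix_,
        residuals=pd.Series(est.residuals_, index=rates.df.index),
        rmse=est.rmse_,
        mae=est.mae_,
        n_train=len(variants),
        estimator=est,
    )


def predict_kflip(weights: WeightMatrix, variant: AttVariant | str) -> float:
    """k_flip of a variant under the product model (WT -> exactly 1)."""
    return float(10.0 ** weights.variant_log10(variant))


def train_val_split(
    rates: RateTable,
    n_total: int,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[RateTable, RateTable]:
    """Sample ``n_total`` variants and split train/validation.

    ``n_train = floor(train_fraction * n_total + 0.5)`` (200 at 0.7 -> 140).
    When present, WT is always sampled and placed in the training set (it
    anchors the gauge). Deterministic for a given seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    variants = rates.df.index.to_numpy(dtype=str)
    if n_total > len(variants):
        raise ValueError(f"n_total={n_total} exceeds table size {len(variants)}")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_fraction * n_total + 0.5))

    if rates.wt in rates.df.index:
        others = variants[variants != rates.wt]
        chosen = rng.choice(others, size=n_total - 1, replace=False)
        rng.shuffle(chosen)
        train = np.concatenate([[rates.wt], chosen[: n_train - 1]])
        val = chosen[n_train - 1:]
    else:
        chosen = rng.choice(variants, size=n_total, replace=False)
        rng.shuffle(chosen)
        train, val = chosen[:n_train], chosen[n_train:]
    return rates.subset(train), rates.subset(val)


@dataclass
class PredictionErrors:
    """Per-variant (predicted - experimental) log10 k_flip with summaries."""

    errors: pd.Series
    mae: float
    rmse: float
    n: int
    n_unidentified: int = 0


def prediction_errors(
    weights: WeightMatrix,
    rates: RateTable,
    on_unidentified: str = "raise",
) -> PredictionErrors:
    """Evaluate model predictions against experimental rates.

    ``on_unidentified`` — ``"raise"`` (default) propagates the error when a
    variant carries an unidentified weight; ``"drop"`` excludes such variants
    and tallies them.
    """
    preds, kept = [], []
    n_unid = 0
    for v in rates.df.index:
        try:
            preds.append(weights.variant_log10(v))
            kept.append(v)
        except UnidentifiedWeightError:
            if on_unidentified == "drop":
                n_unid += 1
            else:
                raise
    if not kept:
        raise ValueError("no predictable variants in the rate table")
    exp = rates.df.loc[kept, "log10_k_flip"].to_numpy(dtype=float)
    err = pd.Series(np.asarray(preds) - exp, index=pd.Index(kept, name="variant"))
    return PredictionErrors(
        errors=err,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        n=len(kept),
        n_unidentified=n_unid,
    )


@dataclass
class SensitivityCurve:
    """Train/validation error and weight dispersion vs training-set size."""

    summary: pd.DataFrame  # per size: train_mae, val_mae, n_underdetermined
    weight_sd: pd.DataFrame  # per feature x size: sd of log10 W across replicates
    replicates: int


def sensitivity_curve(
    rates: RateTable,
    design: LibraryDesign,
    sizes: Sequence[int],
    replicates: int = 5,
    seed: int = 0,
    train_fraction: float = 0.7,
    alpha: float = 0.0,
) -> SensitivityCurve:
    """Sweep the number of sequences used to train the model.

    For each size and replicate: sample that many sequences, split 70/30, fit,
    and record train/validation MAE; the dispersion of each identifiable
    log-weight across replicates measures parameter convergence. Sizes below
    the number of free parameters are the deliberate overfitting regime and
    are flagged, not refused.
    """
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > len(rates):
        raise ValueError("largest size exceeds the rate table")
    n_params = 3 * design.n_positions
    ss = np.random.SeedSequence(seed)
    rows = []
    sd_cols = {}
    for size in sizes:
        train_maes, val_maes, n_under = [], [], 0
        coefs = []
        for child in ss.spawn(replicates):
            rep_seed = int(child.generate_state(1)[0] % 2**31)
            train, val = train_val_split(rates, size, train_fraction, seed=rep_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_weights(train, design, alpha=alpha)
            if fit.estimator.rank_deficient_ or len(train) < n_params:
                n_under += 1
            train_maes.append(fit.mae)
            try:
                val_err = prediction_errors(fit.weights, val, on_unidentified="drop")
                val_maes.append(val_err.mae)
            except ValueError:
                # tiny training sets can leave every validation variant on
                # unidentified weights; recorded as missing, not zero
                val_maes.append(np.nan)
            coefs.append(fit.estimator.coef_)
        coefs = np.vstack(coefs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN columns
            sd_cols[size] = np.nanstd(coefs, axis=0)
        rows.append(
            {
                "size": size,
                "train_mae": float(np.mean(train_maes)),
                "val_mae": float(np.nanmean(val_maes)),
                "n_underdetermined": n_under,
            }
        )
    feature_names = OneHotVariantEncoder(design=design).fit(None).feature_names_out_
    weight_sd = pd.DataFrame(sd_cols, index=feature_names)
    return SensitivityCurve(
        summary=pd.DataFrame(rows), weight_sd=weight_sd, replicates=replicates
    )


def simulate_frequency_profile(
    kflips: np.ndarray | pd.Series | RateTable,
    naive: Optional[np.ndarray] = None,
    rate_scale: float = 5e-5,
    reaction_time: float = 5.0,
    saturation_b: float = 0.0,
) -> np.ndarray:
    """Expected flipped-pool frequencies, sorted descending.

    Forward-simulates the selection from (predicted) rate constants: each
    variant flips a fraction ``F = 1 - exp(-rate_scale*k*t)`` of its
    molecules, and the flipped pool is ``naive * F`` renormalized. The result
    is a rank-frequency curve for overlay against observed NGS profiles.
    """
    if isinstance(kflips, RateTable):
        k = kflips.df["k_flip"].to_numpy(dtype=float)
    else:
        k = np.asarray(kflips, dtype=float)
    if naive is None:
        naive = np.full(k.shape, 1.0 / k.size)
    naive = np.asarray(naive, dtype=float)
    F = flipped_fractions(k, rate_scale, reaction_time, saturation_b)
    pool = naive * F
    total = pool.sum()
    if total <= 0:
        raise ValueError("no flipping occurs under these conditions")
    return np.sort(pool / total)[::-1]
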