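"""End-to-end synthetic benchmark: selection -> FASTQ -> counts -> rates ->
weight-score fit -> validation.

This is the package's self-contained analog of the real experiment: simulate
a library-2 selection under known ground-truth weights, sequence the flipped
pool, run the exact analysis pipeline on the resulting FASTQ, and compare the
fitted model against the truth and against a held-out validation set.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import counts as ngs
from .design import LIBRARY2, LibraryDesign
from .model import (
    FitResult,
    PredictionErrors,
    fit_weights,
    predict_kflip,
    prediction_errors,
    train_val_split,
)
from .rates import RateTable, freq_to_kflip
from .simulate import (
    GroundTruth,
    SelectionConfig,
    generate_ground_truth,
    sample_reads,
    simulate_selection,
)

__all__ = ["BenchmarkResult", "library2_selection_benchmark", "selection_to_rates"]


@dataclass
class BenchmarkResult:
    """Everything measured by one synthetic selection-and-fit round trip."""

    truth: GroundTruth
    rates: RateTable
    fit: FitResult
    val_errors: PredictionErrors
    train_errors: PredictionErrors
    wt_predicted_kflip: float
    weight_recovery_r2: float
    n_identified_weights: int
    total_flipped_fraction: float
    reads_kept: int
    reads_total: int


def selection_to_rates(
    truth: GroundTruth,
    config: SelectionConfig,
    workdir,
    top: Optional[int] = 3000,
    sample_naive: bool = False,
) -> tuple[RateTable, ngs.FrequencyTable, ngs.FilterResult, dict]:
    """Run one selection through FASTQ sampling and back to a rate table.

    The top-``top`` variants by count are analyzed (low-count frequencies are
    unreliable); the WT row is appended from the full table when it falls
    outside the cut, since WT anchors the relative-rate gauge.
    """
    workdir = Path(workdir)
    result = simulate_selection(truth, config)
    out = sample_reads(
        result,
        config,
        workdir / "selected.fastq",
        workdir / "naive.fastq" if sample_naive else None,
    )
    filt = ngs.filter_and_extract(ngs.read_fastq(workdir / "selected.fastq"), truth.design)
    table = ngs.count_variants(filt)
    wt = "".join(truth.design.wt_bases)
    if top is not None and top < len(table):
        sub = ngs.top_n(table, top)
        if wt not in sub and wt in table:
            sub = ngs.FrequencyTable(
                df=table.df.loc[list(sub.df.index) + [wt]],
                total_reads=table.total_reads,
                rejected=table.rejected,
                is_subset=True,
            )
        table = sub
    rates = freq_to_kflip(
        table, wt, mode="linear", reaction_time=config.reaction_time
    )
    out["selection"] = result
    return rates, table, filt, out


def library2_selection_benchmark(
    seed: int = 1,
    design: LibraryDesign = LIBRARY2,
    depth: int = 500_000,
    base_error_rate: float = 0.0,
    rate_scale: float = 5e-5,
    reaction_time: float = 5.0,
    weight_low: float = 0.01,
    weight_high: float = 4.0,
    top: int = 3000,
    n_sample: int = 200,
    train_fraction: float = 0.7,
    workdir=None,
) -> BenchmarkResult:
    """Simulate a library-2 selection and evaluate the fitted weight model.

    Defaults follow the reference study conditions: 9 randomized positions,
    ground-truth weights log-uniform on [0.01, 4], 5-min reaction deep in the
    initial-rate regime, 5x10^5 reads, analysis restricted to the top 3000
    variants, 200 sequences split 140/60 into training and validation.
    """
    seeds = np.random.SeedSequence(seed).generate_state(3).astype(np.int64) % 2**31
    truth = generate_ground_truth(
        design, seed=int(seeds[0]), weight_low=weight_low, weight_high=weight_high
    )
    config = SelectionConfig(
        reaction_time=reaction_time,
        rate_scale=rate_scale,
        read_depth=depth,
        base_error_rate=base_error_rate,
        seed=int(seeds[1]),
    )

    def _run(wd):
        rates, table, filt, out = selection_to_rates(truth, config, wd, top=top)
        train, val = train_val_split(
            rates, n_total=n_sample, train_fraction=train_fraction, seed=int(seeds[2])
        )
        fit = fit_weights(train, design)
        val_err = prediction_errors(fit.weights, val, on_unidentified="drop")
        train_err = prediction_errors(fit.weights, train, on_unidentified="raise")

        # parameter recovery: fitted vs true log10-weights over identified entries
        fitted = fit.weights.log10[:, 1:].ravel()
        true = truth.true_weights.log10[:, 1:].ravel()
        ok = np.isfinite(fitted)
        r2 = float(np.corrcoef(fitted[ok], true[ok])[0, 1] ** 2) if ok.sum() > 1 else np.nan

        return BenchmarkResult(
            truth=truth,
            rates=rates,
            fit=fit,
            val_errors=val_err,
            train_errors=train_err,
            wt_predicted_kflip=predict_kflip(fit.weights, design.wt_variant()),
            weight_recovery_r2=r2,
            n_identified_weights=int(ok.sum()),
            total_flipped_fraction=out["selection"].total_flipped_fraction,
            reads_kept=filt.n_kept,
            reads_total=filt.total_reads,
        )

    if workdir is not None:
        return _run(workdir)
    with tempfile.TemporaryDirectory() as wd:
        return _run(wd)
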