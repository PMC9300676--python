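"""FASTQ -> per-variant frequency tables, base percentages, enrichment scores.

The selection readout is an amplicon pool: every read should be the attP-L
half-site with library bases substituted at the design's variable positions.
Reads are refined exactly as in the original analysis — a read is kept iff it
has the right length, contains only A/C/G/T, and matches the reference at
every constant (non-variable) position — then deduplicated into per-variant
occurrence counts. The enrichment score of base j at position i is the ratio
of its read-weighted percentage in the selected pool to that in the naïve
library.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import BASE_CODE_LUT, BASES, LibraryDesign, codes_to_strings

__all__ = [
    "FrequencyTable",
    "PositionBaseMatrix",
    "EnrichmentMatrix",
    "FilterResult",
    "read_fastq",
    "filter_and_extract",
    "count_variants",
    "base_percentages",
    "enrichment_scores",
    "top_n",
]


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(id, sequence, quality)`` records from a FASTQ(.gz) file.

    Malformed records (truncated, or sequence/quality length mismatch) raise
    ``ValueError`` from the underlying parser.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


@dataclass
class FilterResult:
    """Kept variants plus the rejection tally of a read-refinement pass."""

    variants: np.ndarray  # array of variant base strings
    total_reads: int
    rejected: dict[str, int]

    @property
    def n_kept(self) -> int:
        return int(self.variants.size)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def filter_and_extract(
    reads: Iterable, design: LibraryDesign, try_revcomp: bool = False
) -> FilterResult:
    """Refine reads against the design and project them to variants.

    A read is kept iff its length equals the reference half-site length, all
    bases are A/C/G/T, and every constant (non-variable) position matches the
    reference exactly. Rejections are tallied by reason
    (``length-mismatch`` / ``ambiguous-base`` / ``constant-position-mismatch``),
    never raised. ``reads`` may be FASTQ records or plain sequences.

    With ``try_revcomp`` the reverse complement of a failing read is also
    tried (amplicon orientation is assumed fixed by default).
    """
    seqs: list[str] = []
    for r in reads:
        seqs.append(r[1] if isinstance(r, (tuple, list)) else str(r))
    total = len(seqs)
    tally: Counter[str] = Counter()

    L = design.halfsite_length
    var_idx = np.array([p - 1 for p in design.variable_positions], dtype=np.intp)
    const_idx = np.array(
        [i for i in range(L) if i + 1 not in design.variable_positions], dtype=np.intp
    )
    ref_codes = BASE_CODE_LUT[
        np.frombuffer(design.reference_halfsite.encode("ascii"), dtype=np.uint8)
    ]

    def _refine(candidates: list[str]):
        """Vectorized refinement; returns (kept_codes, fail_reasons, fail_seqs)."""
        if not candidates:
            return np.zeros((0, len(var_idx)), np.uint8), [], []
        lens = np.fromiter((len(s) for s in candidates), dtype=np.intp, count=len(candidates))
        ok_len = lens == L
        arr = np.array(candidates, dtype=object)
        fail_reasons = ["length-mismatch"] * int((~ok_len).sum())
        fail_seqs = list(arr[~ok_len])
        good = list(arr[ok_len])
        if not good:
            return np.zeros((0, len(var_idx)), np.uint8), fail_reasons, fail_seqs
        buf = np.frombuffer("".join(good).upper().encode("latin-1"), dtype=np.uint8)
        codes = BASE_CODE_LUT[buf].reshape(-1, L)
        ambig = (codes == 255).any(axis=1)
        mismatch = (codes[:, const_idx] != ref_codes[const_idx]).any(axis=1)
        reject = ambig | mismatch
        for i in np.flatnonzero(reject):
            fail_reasons.append(
                "ambiguous-base" if ambig[i] else "constant-position-mismatch"
            )
            fail_seqs.append(good[i])
        return codes[~reject][:, var_idx], fail_reasons, fail_seqs

    kept_codes, reasons, failed = _refine(seqs)
    if try_revcomp and failed:
        retry = [
            _revcomp(s) if set(s.upper()) <= set(BASES) else s for s in failed
        ]
        kept2, reasons2, _ = _refine(retry)
        # reasons2 corresponds to still-failing reads; original reasons kept
        kept_codes = np.vstack([kept_codes, kept2])
        tally.update(reasons2)
    else:
        tally.update(reasons)

    variants = codes_to_strings(kept_codes) if kept_codes.size else np.array([], dtype=str)
    return FilterResult(variants=variants, total_reads=total, rejected=dict(tally))


@dataclass
class FrequencyTable:
    """Per-variant occurrence counts and frequencies over refined reads.

    ``df`` is indexed by the variant base string with columns ``count`` and
    ``frequency``; frequencies are counts over the *kept* read total and are
    retained (not renormalized) when a subset is taken with :func:`top_n`.
    """

    df: pd.DataFrame
    total_reads: int
    rejected: dict[str, int] = field(default_factory=dict)
    is_subset: bool = False

    def __post_init__(self):
        if self.df.index.has_duplicates:
            raise ValueError("duplicate variants in frequency table")
        if (self.df["count"] < 1).any():
            raise ValueError("counts must be >= 1 for listed variants")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant) -> bool:
        return str(variant) in self.df.index

    def frequency(self, variant) -> float:
        return float(self.df.at[str(variant), "frequency"])

    def count(self, variant) -> int:
        return int(self.df.at[str(variant), "count"])

    def renormalized(self) -> pd.Series:
        """Frequencies renormalized within this (sub)table."""
        f = self.df["frequency"]
        return f / f.sum()

    def subset(self, variants: Sequence[str]) -> "FrequencyTable":
        """Row subset (original frequencies retained)."""
        return FrequencyTable(
            df=self.df.loc[list(variants)].copy(),
            total_reads=self.total_reads,
            rejected=self.rejected,
            is_subset=True,
        )

    def to_tsv(self, path) -> None:
        out = self.df.reset_index()
        out.columns = ["variant", "count", "frequency"]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant": str})
        df = df.set_index("variant")
        total = int(df["count"].sum())
        return cls(df=df[["count", "frequency"]], total_reads=total)


def count_variants(variants) -> FrequencyTable:
    """Exact multiset count of variants; frequencies over the kept total.

    Accepts a :class:`FilterResult`, an array of variant strings, or any
    iterable of variants. Raises on empty input (no denominator).
    """
    rejected: dict[str, int] = {}
    if isinstance(variants, FilterResult):
        rejected = variants.rejected
        arr = variants.variants
    else:
        arr = np.asarray(
            [str(v) for v in variants] if not isinstance(variants, np.ndarray) else variants,
            dtype=str,
        )
    if arr.size == 0:
        raise ValueError("cannot build a frequency table from zero kept reads")
    uniq, counts = np.unique(arr, return_counts=True)
    order = np.lexsort((uniq, -counts))  # count desc, variant asc
    uniq, counts = uniq[order], counts[order]
    total = int(counts.sum())
    df = pd.DataFrame(
        {"count": counts.astype(int), "frequency": counts / total},
        index=pd.Index(uniq, name="variant"),
    )
    return FrequencyTable(df=df, total_reads=total, rejected=rejected)


@dataclass
class PositionBaseMatrix:
    """Read-weighted percentage of each base at each variable position."""

    df: pd.DataFrame  # index = variable position (1-based), columns = A,C,G,T
    design_name: str = ""

    def __post_init__(self):
        sums = self.df.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError("base percentages must sum to 100 at every position")

    def to_tsv(self, path) -> None:
        self.df.rename_axis("position").to_csv(path, sep="\t")


def base_percentages(table: FrequencyTable, design: LibraryDesign) -> PositionBaseMatrix:
    """Percentage of each nucleotide at each randomized position, weighted by
    read count."""
    if len(table) == 0:
        raise ValueError("empty frequency table")
    variants = table.df.index.to_numpy(dtype=str)
    counts = table.df["count"].to_numpy(dtype=float)
    p = design.n_positions
    chars = variants.astype(f"U{p}").view("U1").reshape(len(variants), p)
    total = counts.sum()
    pct = np.zeros((p, 4))
    for j, b in enumerate(BASES):
        pct[:, j] = ((chars == b) * counts[:, None]).sum(axis=0)
    pct = 100.0 * pct / total
    df = pd.DataFrame(pct, index=list(design.variable_positions), columns=list(BASES))
    return PositionBaseMatrix(df=df, design_name=design.name)


@dataclass
class EnrichmentMatrix:
    """Selected/naïve percentage ratio per position x base.

    Entries with a zero naïve percentage are undefined: NaN in ``df`` and
    flagged in ``undefined``.
    """

    df: pd.DataFrame
    undefined: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.df.rename_axis("position").to_csv(path, sep="\t")


def enrichment_scores(
    selected: PositionBaseMatrix, naive: PositionBaseMatrix
) -> EnrichmentMatrix:
    """E_ij = selected%_ij / naive%_ij, with zero-naïve entries flagged."""
    if not selected.df.index.equals(naive.df.index):
        raise ValueError("selected and naïve matrices cover different positions")
    naive_vals = naive.df.to_numpy()
    undef = naive_vals == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        e = selected.df.to_numpy() / naive_vals
    e[undef] = np.nan
    df = pd.DataFrame(e, index=selected.df.index, columns=selected.df.columns)
    return EnrichmentMatrix(
        df=df,
        undefined=pd.DataFrame(undef, index=df.index, columns=df.columns),
    )


def top_n(table: FrequencyTable, n: int) -> FrequencyTable:
    """The n highest-count variants (ties at the cutoff broken by
    lexicographic variant order). Frequencies are retained from the full
    table; use :meth:`FrequencyTable.renormalized` for a renormalized view.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = table.df
    if n >= len(df):
        import warnings

        if n > len(df):
            warnings.warn(
                f"requested top {n} of a table with {len(df)} variants; returning all"
            )
        sub = df.copy()
    else:
        order = np.lexsort((df.index.to_numpy(), -df["count"].to_numpy()))
        sub = df.iloc[order[:n]].copy()
    return FrequencyTable(
        df=sub, total_reads=table.total_reads, rejected=table.rejected, is_subset=True
    )
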