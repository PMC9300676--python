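"""Library designs, attP-L variants, and one-hot encodings.

A large serine recombinase such as Bxb1 recognizes an ~48-bp attP site whose
left quasi-palindromic half ("attP-L") is bound by one recombinase monomer.
Saturation-mutagenesis libraries randomize a handful of positions within that
half-site; everything downstream (read filtering, counting, rate conversion,
weight-score fitting) is phrased in terms of a :class:`LibraryDesign` — the set
of randomized positions and their wild-type bases — and :class:`AttVariant` —
the bases a library member carries at exactly those positions.

Positions are 1-based along the half-site, numbered 5'→3' from the central
dinucleotide outward. Two designs ship with the package:

* ``library1`` — 10 consecutive randomized positions 9–18;
* ``library2`` — the 9 asymmetric positions 3, 5, 8, 11, 12, 14, 15, 16, 17,
  keeping the conserved bases 9G, 10T, 18A and the putatively conserved 19C
  fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

BASES = "ACGT"
_BASE_SET = frozenset(BASES)

#: byte-code lookup: ASCII code of A/C/G/T -> 0..3, everything else -> 255
BASE_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _k, _b in enumerate(BASES):
    BASE_CODE_LUT[ord(_b)] = _k
#: inverse lookup: 0..3 -> ASCII code of A/C/G/T
BASE_ASCII = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8).copy()


class DesignError(ValueError):
    """Invalid library design or variant specification."""


class HalfsiteRejection(ValueError):
    """A half-site sequence incompatible with the design (reason in ``reason``)."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class LibraryDesign:
    """A saturation-mutagenesis scheme on the attP-L half-site.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"library2"``.
    variable_positions : tuple of int
        1-based randomized positions, strictly increasing.
    wt_bases : tuple of str
        Wild-type base at each variable position.
    conserved_positions : mapping int -> str
        Positions required for recognition specificity (checked when
        projecting half-sites onto the design); disjoint from the
        variable positions.
    reference_halfsite : str
        Base string covering positions ``1..L``; must agree with
        ``wt_bases`` and ``conserved_positions``.
    """

    name: str
    variable_positions: tuple[int, ...]
    wt_bases: tuple[str, ...]
    conserved_positions: Mapping[int, str] = field(default_factory=dict)
    reference_halfsite: str = ""

    def __post_init__(self):
        pos = tuple(int(p) for p in self.variable_positions)
        wt = tuple(str(b).upper() for b in self.wt_bases)
        object.__setattr__(self, "variable_positions", pos)
        object.__setattr__(self, "wt_bases", wt)
        object.__setattr__(
            self, "conserved_positions",
            {int(p): str(b).upper() for p, b in self.conserved_positions.items()},
        )
        if len(pos) != len(set(pos)) or list(pos) != sorted(pos):
            raise DesignError("variable positions must be distinct and ascending")
        if len(wt) != len(pos):
            raise DesignError("one WT base required per variable position")
        for b in itertools.chain(wt, self.conserved_positions.values()):
            if b not in _BASE_SET:
                raise DesignError(f"invalid base {b!r}")
        if set(pos) & set(self.conserved_positions):
            raise DesignError("variable and conserved position sets overlap")
        ref = self.reference_halfsite.upper()
        object.__setattr__(self, "reference_halfsite", ref)
        L = len(ref)
        if L < max(itertools.chain(pos, self.conserved_positions, [1])):
            raise DesignError("reference half-site shorter than the largest position")
        if any(c not in _BASE_SET for c in ref):
            raise DesignError("reference half-site contains non-ACGT symbols")
        for p, b in zip(pos, wt):
            if ref[p - 1] != b:
                raise DesignError(f"reference disagrees with WT base at position {p}")
        for p, b in self.conserved_positions.items():
            if ref[p - 1] != b:
                raise DesignError(f"reference disagrees with conserved base at position {p}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_positions(self) -> int:
        return len(self.variable_positions)

    @property
    def halfsite_length(self) -> int:
        return len(self.reference_halfsite)

    @property
    def library_size(self) -> int:
        return 4 ** self.n_positions

    def wt_variant(self) -> "AttVariant":
        return AttVariant("".join(self.wt_bases))

    def position_index(self, position: int) -> int:
        """0-based index of a 1-based variable position."""
        try:
            return self.variable_positions.index(position)
        except ValueError:
            raise DesignError(f"position {position} is not variable in {self.name}") from None

    def base_columns(self) -> tuple[tuple[str, str, str, str], ...]:
        """Per-position column order: column 1 = WT base, then the three
        non-WT bases alphabetically."""
        cols = []
        for b in self.wt_bases:
            others = tuple(x for x in BASES if x != b)
            cols.append((b,) + others)
        return tuple(cols)

    def halfsite(self, variant: "AttVariant") -> str:
        """Full half-site sequence with the variant's bases substituted."""
        validate_variant(variant, self)
        seq = list(self.reference_halfsite)
        for p, b in zip(self.variable_positions, variant.bases):
            seq[p - 1] = b
        return "".join(seq)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variable_positions": list(self.variable_positions),
            "wt_bases": list(self.wt_bases),
            "conserved_positions": dict(self.conserved_positions),
            "reference_halfsite": self.reference_halfsite,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LibraryDesign":
        return cls(
            name=d["name"],
            variable_positions=tuple(d["variable_positions"]),
            wt_bases=tuple(d["wt_bases"]),
            conserved_positions=dict(d.get("conserved_positions", {})),
            reference_halfsite=d["reference_halfsite"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LibraryDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class AttVariant:
    """Bases of a library member at the design's variable positions only."""

    bases: str

    def __post_init__(self):
        object.__setattr__(self, "bases", self.bases.upper())

    def __str__(self) -> str:
        return self.bases

    def mutations(self, design: LibraryDesign) -> list[str]:
        """Mutation tokens (``G5T`` style) relative to the design's WT."""
        validate_variant(self, design)
        return [
            f"{wt}{pos}{b}"
            for pos, wt, b in zip(design.variable_positions, design.wt_bases, self.bases)
            if b != wt
        ]


def validate_variant(variant: AttVariant, design: LibraryDesign) -> None:
    if len(variant.bases) != design.n_positions:
        raise DesignError(
            f"variant length {len(variant.bases)} != {design.n_positions} variable positions"
        )
    bad = set(variant.bases) - _BASE_SET
    if bad:
        raise DesignError(f"variant contains non-ACGT bases {sorted(bad)}")


# ---------------------------------------------------------------------------
# reference designs
# ---------------------------------------------------------------------------

# attP-L positions 1..19. Bases fixed by the half-site alignment:
# 3G 5G 8G 9G 10T 11T 12G 13A 14C 15C 16A 17G 18A 19C. Positions 1, 2, 4, 6, 7
# are placeholders ("A"): they are constant in both shipped designs and never
# enter the model; amplicon filtering only requires that reads match them
# consistently.
REFERENCE_HALFSITE = "AAGAGAAGGTTGACCAGAC"

LIBRARY1 = LibraryDesign(
    name="library1",
    variable_positions=tuple(range(9, 19)),
    wt_bases=("G", "T", "T", "G", "A", "C", "C", "A", "G", "A"),
    conserved_positions={},
    reference_halfsite=REFERENCE_HALFSITE,
)

LIBRARY2 = LibraryDesign(
    name="library2",
    variable_positions=(3, 5, 8, 11, 12, 14, 15, 16, 17),
    wt_bases=("G", "G", "G", "T", "G", "C", "C", "A", "G"),
    conserved_positions={9: "G", 10: "T", 18: "A", 19: "C"},
    reference_halfsite=REFERENCE_HALFSITE,
)

_DESIGNS = {"library1": LIBRARY1, "library2": LIBRARY2}


def get_design(name_or_path: str) -> LibraryDesign:
    """Look up a shipped design by name, or load one from a YAML file."""
    if name_or_path in _DESIGNS:
        return _DESIGNS[name_or_path]
    return LibraryDesign.from_yaml(name_or_path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def parse_mutations(spec: str, design: LibraryDesign) -> AttVariant:
    """Build a variant from comma-separated mutation tokens like ``G5T,G12A``.

    An empty specification yields the WT variant. Each token must name a
    variable position, state the correct WT base, and appear at most once.
    """
    bases = list(design.wt_bases)
    seen: set[int] = set()
    for token in (t.strip() for t in spec.split(",") if t.strip()):
        if len(token) < 3:
            raise DesignError(f"malformed mutation token {token!r}")
        wt, new = token[0].upper(), token[-1].upper()
        try:
            pos = int(token[1:-1])
        except ValueError:
            raise DesignError(f"malformed mutation token {token!r}") from None
        if new not in _BASE_SET or wt not in _BASE_SET:
            raise DesignError(f"invalid base in mutation token {token!r}")
        if pos in seen:
            raise DesignError(f"duplicate position {pos} in mutation list")
        seen.add(pos)
        idx = design.position_index(pos)  # raises on unknown/non-variable position
        if design.wt_bases[idx] != wt:
            raise DesignError(
                f"WT base mismatch in {token!r}: design has "
                f"{design.wt_bases[idx]} at position {pos}"
            )
        bases[idx] = new
    return AttVariant("".join(bases))


def variant_from_halfsite(sequence: str, design: LibraryDesign) -> AttVariant:
    """Project a full half-site sequence onto the design's variable positions.

    Raises :class:`HalfsiteRejection` with a machine-readable ``reason`` on
    length mismatch, non-ACGT symbols, or disagreement at a conserved
    position.
    """
    seq = sequence.upper()
    if len(seq) != design.halfsite_length:
        raise HalfsiteRejection(
            "length-mismatch", f"{len(seq)} != {design.halfsite_length}"
        )
    bad = set(seq) - _BASE_SET
    if bad:
        raise HalfsiteRejection("ambiguous-base", ",".join(sorted(bad)))
    for p, b in design.conserved_positions.items():
        if seq[p - 1] != b:
            raise HalfsiteRejection(
                "conserved-base-violation", f"position {p}: {seq[p - 1]} != {b}"
            )
    return AttVariant("".join(seq[p - 1] for p in design.variable_positions))


@dataclass(frozen=True)
class OneHotMatrix:
    """P x 4 binary encoding of a variant; column 1 holds the WT base."""

    matrix: np.ndarray
    column_bases: tuple[tuple[str, str, str, str], ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise DesignError("one-hot matrix must be P x 4")
        if not np.array_equal(m.sum(axis=1), np.ones(m.shape[0], dtype=np.int8)):
            raise DesignError("each one-hot row must contain exactly one 1")


def one_hot_encode(variant: AttVariant, design: LibraryDesign) -> OneHotMatrix:
    """Encode a variant as a P x 4 one-hot matrix (WT base -> column 1)."""
    validate_variant(variant, design)
    cols = design.base_columns()
    m = np.zeros((design.n_positions, 4), dtype=np.int8)
    for i, b in enumerate(variant.bases):
        m[i, cols[i].index(b)] = 1
    return OneHotMatrix(m, cols)


def enumerate_library(
    design: LibraryDesign, limit: int = 4 ** 11
) -> Iterator[AttVariant]:
    """Yield every variant of the design once, in lexicographic (ACGT) order.

    ``limit`` guards against runaway enumeration of large designs.
    """
    if design.library_size > limit:
        raise DesignError(
            f"library size {design.library_size} exceeds limit {limit}"
        )
    for combo in itertools.product(BASES, repeat=design.n_positions):
        yield AttVariant("".join(combo))


def library_codes(design: LibraryDesign) -> np.ndarray:
    """All 4^P variants as a (4^P, P) uint8 array of base codes (A=0..T=3),
    rows in the same lexicographic order as :func:`enumerate_library`."""
    p = design.n_positions
    idx = np.unravel_index(np.arange(4 ** p), (4,) * p)
    return np.stack(idx, axis=1).astype(np.uint8)


def codes_to_strings(codes: np.ndarray) -> np.ndarray:
    """Decode a (n, P) base-code array into an array of base strings."""
    codes = np.ascontiguousarray(codes, dtype=np.uint8)
    n, p = codes.shape
    ascii_arr = BASE_ASCII[codes]
    return ascii_arr.view(f"S{p}").ravel().astype(f"U{p}")


def strings_to_codes(variants: Sequence[str] | np.ndarray) -> np.ndarray:
    """Encode equal-length base strings into a (n, P) uint8 code array."""
    arr = np.asarray(variants, dtype=str)
    if arr.size == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    p = len(arr.flat[0])
    buf = np.frombuffer("".join(arr.tolist()).encode("latin-1"), dtype=np.uint8)
    codes = BASE_CODE_LUT[buf].reshape(-1, p)
    if (codes == 255).any():
        raise DesignError("non-ACGT symbol in variant strings")
    return codes
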