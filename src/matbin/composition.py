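"""Per-scaffold oligonucleotide composition and G+C statistics.

Counts every DNA word of lengths ``k_min..k_max`` (default 3..6) with a
sliding window, skipping windows that contain ambiguous bases, and
normalizes each per-k block by its number of valid windows so that each
block is an exact probability simplex. Also builds taxon-stratified G+C
frequency spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from matbin.seqio import ScaffoldRecord

__all__ = [
    "CompositionVector",
    "GCSpectrum",
    "gc_content",
    "revcomp",
    "count_oligos",
    "normalize",
    "composition_vector",
    "composition_matrix",
    "feature_names",
    "gc_spectrum",
]

_ENCODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVacgtrykmbdhv", "TGCAYRMKVHDBtgcayrmkvhdb")

_BASES = "ACGT"


def revcomp(sequence: str) -> str:
    """Reverse complement (IUPAC-aware for the common ambiguity codes)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); ambiguous bases excluded.

    Returns ``nan`` when the sequence has no unambiguous base. Raises on
    an empty sequence.
    """
    if len(sequence) == 0:
        raise ValueError("gc_content of empty sequence is undefined")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def _encode(sequence: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]


def _word(code: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(letters))


def _revcomp_codes(k: int) -> np.ndarray:
    """code -> code of reverse complement, for all 4**k words."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def feature_names(k_min: int = 3, k_max: int = 6, collapse_revcomp: bool = False) -> list[str]:
    """Ordered word labels matching :func:`composition_matrix` columns."""
    names: list[str] = []
    for k in range(k_min, k_max + 1):
        if collapse_revcomp:
            rc = _revcomp_codes(k)
            keep = np.flatnonzero(np.arange(4**k) <= rc)
            names.extend(_word(int(c), k) for c in keep)
        else:
            names.extend(_word(c, k) for c in range(4**k))
    return names


def _count_arrays(
    enc: np.ndarray, k_min: int, k_max: int, collapse_revcomp: bool
) -> tuple[dict[int, np.ndarray], dict[int, int]]:
    """Per-k count vectors (over canonical word codes) and valid-window counts."""
    counts: dict[int, np.ndarray] = {}
    n_valid: dict[int, int] = {}
    codes = enc.copy()
    valid = enc >= 0
    for k in range(1, k_max + 1):
        if k > 1:
            if len(enc) < k:
                codes = np.empty(0, dtype=np.int64)
                valid = np.empty(0, dtype=bool)
            else:
                codes = (codes[:-1] << 2) + np.where(enc[k - 1 :] >= 0, enc[k - 1 :], 0)
                valid = valid[:-1] & (enc[k - 1 :] >= 0)
        if k < k_min:
            continue
        vc = codes[valid]
        c = np.bincount(vc, minlength=4**k).astype(np.int64)
        n_valid[k] = int(vc.size)
        if collapse_revcomp:
            rc = _revcomp_codes(k)
            pooled = c + np.where(rc != np.arange(4**k), c[rc], 0)
            keep = np.arange(4**k) <= rc
            c = np.where(keep, pooled, 0)
        counts[k] = c
    return counts, n_valid


def count_oligos(
    sequence: str,
    k_min: int = 3,
    k_max: int = 6,
    collapse_revcomp: bool = False,
) -> tuple[dict[str, int], dict[int, int]]:
    """Count all k-mers for each k in ``[k_min, k_max]``.

    Windows containing any non-ACGT symbol are skipped and excluded from
    the valid-window tally. With ``collapse_revcomp`` a word and its
    reverse complement share one count under the lexicographically
    smaller key. A k exceeding the sequence length yields zero counts
    (not an error). Returns ``(counts, n_valid_windows)``.
    """
    if k_min > k_max:
        raise ValueError(f"k_min ({k_min}) > k_max ({k_max})")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if len(sequence) == 0:
        raise ValueError("cannot count oligonucleotides of an empty sequence")
    enc = _encode(sequence)
    arrays, n_valid = _count_arrays(enc, k_min, k_max, collapse_revcomp)
    out: dict[str, int] = {}
    for k in range(k_min, k_max + 1):
        nz = np.flatnonzero(arrays[k])
        for code in nz:
            out[_word(int(code), k)] = int(arrays[k][code])
    return out, n_valid


def normalize(counts: Mapping[str, int], n_valid_windows: Mapping[int, int]) -> dict[str, float]:
    """count / n_valid_windows[len(word)]; zero-window k yields no entries."""
    freqs: dict[str, float] = {}
    for word, c in counts.items():
        nv = n_valid_windows.get(len(word), 0)
        freqs[word] = c / nv if nv > 0 else 0.0
    return freqs


@dataclass
class CompositionVector:
    """Length-normalized word frequencies plus G+C for one scaffold."""

    scaffold_id: str
    k_range: tuple[int, int]
    counts: dict[str, int]
    frequencies: dict[str, float]
    gc: float
    n_valid_windows: dict[int, int]


def composition_vector(
    record: ScaffoldRecord,
    k_min: int = 3,
    k_max: int = 6,
    collapse_revcomp: bool = False,
) -> CompositionVector:
    counts, n_valid = count_oligos(record.sequence, k_min, k_max, collapse_revcomp)
    return CompositionVector(
        scaffold_id=record.id,
        k_range=(k_min, k_max),
        counts=counts,
        frequencies=normalize(counts, n_valid),
        gc=gc_content(record.sequence),
        n_valid_windows=n_valid,
    )


def composition_matrix(
    records: Sequence[ScaffoldRecord],
    k_min: int = 3,
    k_max: int = 6,
    collapse_revcomp: bool = False,
) -> pd.DataFrame:
    """Scaffold x word frequency matrix (rows ordered as input).

    Column blocks for each k each sum to 1 per row (0 when a scaffold has
    no valid window at that k). For k=(3,6) uncollapsed the width is
    4^3+4^4+4^5+4^6 = 5440.
    """
    if not records:
        raise ValueError("no records given")
    cols = feature_names(k_min, k_max, collapse_revcomp)
    X = np.zeros((len(records), len(cols)), dtype=np.float64)
    for i, rec in enumerate(records):
        enc = _encode(rec.sequence)
        arrays, n_valid = _count_arrays(enc, k_min, k_max, collapse_revcomp)
        offset = 0
        for k in range(k_min, k_max + 1):
            c = arrays[k]
            if collapse_revcomp:
                rc = _revcomp_codes(k)
                c = c[np.arange(4**k) <= rc]
            width = c.size
            if n_valid[k] > 0:
                X[i, offset : offset + width] = c / n_valid[k]
            offset += width
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scaffold ids in record collection")
    return pd.DataFrame(X, index=ids, columns=cols)


@dataclass
class GCSpectrum:
    """Histogram of per-record G+C percent, optionally stratified by taxon."""

    bin_edges: np.ndarray  # percent, covering [0, 100]
    strata: dict[str, np.ndarray] = field(default_factory=dict)
    n_undefined: int = 0  # records with no unambiguous base

    @property
    def total(self) -> np.ndarray:
        out = np.zeros(len(self.bin_edges) - 1)
        for counts in self.strata.values():
            out += counts
        return out

    def mode_percent(self) -> float:
        """Left edge + half width of the most populated bin."""
        tot = self.total
        i = int(np.argmax(tot))
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2)


def gc_spectrum(
    records: Iterable[ScaffoldRecord],
    bin_width: float = 1.0,
    stratify_by_taxon: bool = True,
) -> GCSpectrum:
    """Stacked G+C percent histogram; one stratum per taxon label.

    Records without a taxon label (or with stratification off) fall in
    the ``"unassigned"`` stratum. Stratum totals conserve record count
    (records whose G+C is undefined are tallied in ``n_undefined``).
    """
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    by_stratum: dict[str, list[float]] = {}
    n_undefined = 0
    for rec in records:
        gc = gc_content(rec.sequence)
        if math.isnan(gc):
            n_undefined += 1
            continue
        label = rec.taxon if (stratify_by_taxon and rec.taxon) else "unassigned"
        by_stratum.setdefault(label, []).append(gc * 100.0)
    strata = {
        label: np.histogram(vals, bins=edges)[0]
        for label, vals in by_stratum.items()
    }
    return GCSpectrum(bin_edges=edges, strata=strata, n_undefined=n_undefined)
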