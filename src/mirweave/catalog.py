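"""Small-RNA tag cataloguing: collapse, length filter, contaminant removal,
matching against a reference mature-miRNA set with the L/R-shift + substitution
variant nomenclature, length distributions and expression tiers.

Sequences are stored in the DNA alphabet internally (U normalised to T);
the variant suffix grammar is ``<refid>[_L±n][_R±n][_<k>ss<pos><ref><alt>...]``
with at most 2 substitutions and end shifts of at most 2 nt, substitution
positions 1-based on the reference mature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import get_logger

log = get_logger(__name__)

_VALID = set("ACGT")
_COMP = str.maketrans("ACGT", "TGCA")


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class TagCount:
    """A unique small-RNA sequence with per-library read counts."""

    tag: str
    counts: list[int]

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def __len__(self) -> int:
        return len(self.tag)


Catalog = list  # list[TagCount], ordered by (total desc, tag lex)


def collapse_reads(libraries: Sequence[Iterable]) -> Catalog:
    """Collapse per-library read collections into one TagCount per sequence.

    Each library is an iterable of sequences or of (sequence, count) pairs
    (collapsed-tag input); libraries are ordered S1..Sk.  Records containing
    non-nucleotide symbols are skipped and logged.
    """
    k = len(libraries)
    acc: dict[str, np.ndarray] = {}
    skipped = 0
    for s, lib in enumerate(libraries):
        for item in lib:
            seq, count = (item, 1) if isinstance(item, str) else (item[0], int(item[1]))
            seq = _norm(seq)
            if not seq or not set(seq) <= _VALID:
                skipped += 1
                continue
            if seq not in acc:
                acc[seq] = np.zeros(k, dtype=int)
            acc[seq][s] += count
    if skipped:
        log.warning("skipped %d reads with non-nucleotide symbols", skipped)
    tags = [TagCount(seq, counts.tolist()) for seq, counts in acc.items()]
    tags.sort(key=lambda t: (-t.total, t.tag))
    return tags


def filter_by_length(catalog: Catalog, min_len: int = 17, max_len: int = 25) -> Catalog:
    """Keep tags with min_len <= length <= max_len (inclusive); counts untouched."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [t for t in catalog if min_len <= len(t) <= max_len]


def remove_contaminants(catalog: Catalog, contaminants: dict[str, str]) -> tuple[Catalog, Catalog]:
    """Partition the catalog against an rRNA/tRNA/snRNA/snoRNA set.

    A tag is removed iff it occurs as an exact substring of any contaminant
    sequence on either strand.  Returns (kept, removed); kept + removed is the
    input.
    """
    if not contaminants:
        log.warning("empty contaminant set; keeping the whole catalog")
        return list(catalog), []
    haystack = []
    for seq in contaminants.values():
        seq = _norm(seq)
        haystack.append(seq)
        haystack.append(seq.translate(_COMP)[::-1])
    blob = "\n".join(haystack)  # newline separator prevents cross-boundary hits
    kept, removed = [], []
    for t in catalog:
        (removed if t.tag in blob else kept).append(t)
    return kept, removed


# ---------------------------------------------------------------------------
# Variant nomenclature
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(
    r"^(?P<ref>.+?)"
    r"(?:_L(?P<l>[+-]\d+))?"
    r"(?:_R(?P<r>[+-]\d+))?"
    r"(?:_(?P<k>\d+)ss(?P<subs>(?:\d+[ACGT]{2})+))?$"
)
_SUB_RE = re.compile(r"(\d+)([ACGT])([ACGT])")


@dataclass
class VariantName:
    """End-shift / substitution description of a tag relative to a reference.

    ``left``/``right`` are signed end shifts (+ = tag extended beyond the
    reference, - = tag trimmed); substitutions are (1-based reference
    position, reference base, tag base).
    """

    ref_id: str
    left: int = 0
    right: int = 0
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)

    def render(self) -> str:
        parts = [self.ref_id]
        if self.left:
            parts.append(f"L{self.left:+d}")
        if self.right:
            parts.append(f"R{self.right:+d}")
        if self.substitutions:
            subs = "".join(f"{p}{a}{b}" for p, a, b in self.substitutions)
            parts.append(f"{len(self.substitutions)}ss{subs}")
        return "_".join(parts)

    @classmethod
    def parse(cls, name: str) -> "VariantName":
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"unparseable variant name: {name!r}")
        subs = []
        if m.group("subs"):
            subs = [(int(p), a, b) for p, a, b in _SUB_RE.findall(m.group("subs"))]
            if len(subs) != int(m.group("k")):
                raise ValueError(f"substitution count mismatch in {name!r}")
        return cls(m.group("ref"),
                   int(m.group("l") or 0), int(m.group("r") or 0), subs)

    def apply(self, ref_seq: str, left_ext: str = "", right_ext: str = "") -> str:
        """Materialise the tag this name describes from the reference mature.

        Extensions (positive shifts) need flanking bases, supplied via
        ``left_ext``/``right_ext`` (e.g. drawn from the precursor).
        """
        ref_seq = _norm(ref_seq)
        seq = list(ref_seq)
        for pos, ref_base, alt in self.substitutions:
            if seq[pos - 1] != ref_base:
                raise ValueError(f"reference base mismatch at {pos}: "
                                 f"expected {ref_base}, found {seq[pos - 1]}")
            seq[pos - 1] = alt
        core = "".join(seq)
        if self.left > 0:
            if len(left_ext) < self.left:
                raise ValueError("left extension bases required")
            core = left_ext[-self.left:] + core
        elif self.left < 0:
            core = core[-self.left:]
        if self.right > 0:
            if len(right_ext) < self.right:
                raise ValueError("right extension bases required")
            core = core + right_ext[:self.right]
        elif self.right < 0:
            core = core[:self.right]
        return core


def derive_variant(tag: str, ref_id: str, ref_seq: str,
                   max_sub: int = 2, max_shift: int = 2) -> VariantName | None:
    """Best VariantName explaining ``tag`` against one reference, or None.

    Candidates enumerate end shifts (l, r) with |l|,|r| <= max_shift and
    l + r = len(tag) - len(ref); substitutions are counted on the overlapping
    reference positions.  The minimum of (substitutions, |l|+|r|, l, r) wins.
    """
    tag, ref_seq = _norm(tag), _norm(ref_seq)
    delta = len(tag) - len(ref_seq)
    best = None
    for l in range(-max_shift, max_shift + 1):
        r = delta - l
        if abs(r) > max_shift:
            continue
        subs = []
        ok = True
        p_start = 1 + max(0, -l)
        p_end = len(ref_seq) - max(0, -r)
        if p_end < p_start:
            continue
        for p in range(p_start, p_end + 1):
            tb = tag[p - 1 + l]
            rb = ref_seq[p - 1]
            if tb != rb:
                subs.append((p, rb, tb))
                if len(subs) > max_sub:
                    ok = False
                    break
        if not ok:
            continue
        key = (len(subs), abs(l) + abs(r), l, r)
        if best is None or key < best[0]:
            best = (key, VariantName(ref_id, l, r, subs))
    return best[1] if best else None


@dataclass
class MatchResult:
    tag: str
    variant: VariantName | None   # None -> novel candidate

    @property
    def name(self) -> str | None:
        return self.variant.render() if self.variant else None

    @property
    def is_exact(self) -> bool:
        v = self.variant
        return v is not None and not v.left and not v.right and not v.substitutions


def match_known(catalog: Catalog, reference: dict[str, str],
                max_sub: int = 2, max_shift: int = 2) -> dict[str, MatchResult]:
    """Match each tag to the reference mature minimising (substitutions,
    total shift), ties broken by reference id; unmatched tags are flagged
    novel candidates (variant None)."""
    if len(set(reference)) != len(reference):
        raise ValueError("reference ids must be unique")
    out: dict[str, MatchResult] = {}
    ref_items = sorted(reference.items())  # lexicographic tie-break
    for t in catalog:
        best = None
        for rid, rseq in ref_items:
            v = derive_variant(t.tag, rid, rseq, max_sub, max_shift)
            if v is None:
                continue
            key = (len(v.substitutions), abs(v.left) + abs(v.right), rid)
            if best is None or key < best[0]:
                best = (key, v)
        out[t.tag] = MatchResult(t.tag, best[1] if best else None)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def length_distribution(catalog: Catalog, min_len: int = 17, max_len: int = 25) -> pd.DataFrame:
    """Unique (per-tag) and redundant (count-weighted) length histograms."""
    idx = pd.Index(range(min_len, max_len + 1), name="length")
    df = pd.DataFrame(0, index=idx, columns=["unique", "redundant"])
    for t in catalog:
        if len(t) in df.index:
            df.loc[len(t), "unique"] += 1
            df.loc[len(t), "redundant"] += t.total
    return df


def expression_tier(total: int, catalog_mean: float) -> str:
    """Abundance tier: low (<10 reads), high (> catalog mean), else middle."""
    if total < 0:
        raise ValueError("total must be >= 0")
    if total < 10:
        return "low"
    if total > catalog_mean:
        return "high"
    return "middle"


def catalog_table(catalog: Catalog, matches: dict[str, MatchResult] | None = None,
                  library_ids: list[str] | None = None) -> pd.DataFrame:
    """Flatten a catalog (+ optional matches) into the catalog TSV schema."""
    if not catalog:
        return pd.DataFrame(columns=["tag", "length", "total", "match", "tier"])
    k = len(catalog[0].counts)
    library_ids = library_ids or [f"S{i + 1}" for i in range(k)]
    mean_total = float(np.mean([t.total for t in catalog]))
    rows = []
    for t in catalog:
        m = matches.get(t.tag) if matches else None
        rows.append({
            "tag": t.tag, "length": len(t),
            **{lib: c for lib, c in zip(library_ids, t.counts)},
            "total": t.total,
            "match": (m.name if m and m.variant else "novel-candidate") if matches else "",
            "ref_id": (m.variant.ref_id if m and m.variant else "") if matches else "",
            "exact": bool(m.is_exact) if matches else False,
            "tier": expression_tier(t.total, mean_total),
        })
    return pd.DataFrame(rows)
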