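"""Candidate precursor excision, RNA folding, MFE/AMFE/MFEI statistics and
hairpin validation by duplex geometry and read coverage.

The folding engine is injectable.  The default delegates to the ViennaRNA
nearest-neighbour minimum-free-energy model through its Python bindings; a
base-pair-maximisation stub (Nussinov recursion, NOT thermodynamic, MFE
reported as -pairs) is provided for structure-only tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import get_logger

log = get_logger(__name__)

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


# ---------------------------------------------------------------------------
# Folding engines
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    structure: str   # dot-bracket, same length as the sequence
    mfe: float       # kcal/mol (<= 0); stub engine reports -pairs


class ViennaFold:
    """ViennaRNA MFE folding (deterministic, kcal/mol)."""

    def __init__(self):
        try:
            import RNA  # ViennaRNA python bindings
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA python bindings are required for thermodynamic "
                "folding; inject a different engine or install viennarna") from exc
        self._rna = RNA

    def fold(self, sequence: str) -> FoldResult:
        structure, mfe = self._rna.fold(sequence.upper().replace("T", "U"))
        return FoldResult(structure, float(mfe))


class MaxPairStub:
    """Base-pair maximisation (Nussinov, min loop 3).  Non-thermodynamic:
    use only where kcal/mol does not matter."""

    def fold(self, sequence: str) -> FoldResult:
        s = sequence.upper().replace("U", "T")
        n = len(s)
        dp = np.zeros((n + 1, n + 1), dtype=int)
        for span in range(4, n + 1):
            for i in range(0, n - span + 1):
                j = i + span  # half-open [i, j)
                best = dp[i + 1, j]
                for k in range(i + 4, j):
                    if (s[i], s[k]) in _PAIRS:
                        best = max(best, 1 + dp[i + 1, k] + dp[k + 1, j])
                dp[i, j] = best
        struct = ["."] * n

        def trace(i, j):
            while j - i > 3:
                if dp[i, j] == dp[i + 1, j]:
                    i += 1
                    continue
                for k in range(i + 4, j):
                    if (s[i], s[k]) in _PAIRS and dp[i, j] == 1 + dp[i + 1, k] + dp[k + 1, j]:
                        struct[i], struct[k] = "(", ")"
                        trace(i + 1, k)
                        i, j = k + 1, j
                        break
                else:
                    i += 1

        trace(0, n)
        return FoldResult("".join(struct), -float(dp[0, n]))


_DEFAULT_ENGINE = None


def default_engine() -> ViennaFold:
    global _DEFAULT_ENGINE
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = ViennaFold()
    return _DEFAULT_ENGINE


def fold(sequence: str, engine=None) -> FoldResult:
    """Fold an RNA sequence; deterministic for fixed input."""
    seq = sequence.upper()
    if not set(seq) <= set("ACGUT"):
        raise ValueError("fold requires an RNA/DNA alphabet sequence")
    engine = engine or default_engine()
    result = engine.fold(sequence)
    if len(result.structure) != len(sequence):
        raise RuntimeError("folding engine returned a structure of wrong length")
    return result


def pair_table(structure: str) -> list[int]:
    """1-based pairing partners from dot-bracket; 0 = unpaired."""
    partner = [0] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            partner[i] = j + 1
            partner[j] = i + 1
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


# ---------------------------------------------------------------------------
# Candidate excision and hairpin statistics
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    start: int   # 1-based inclusive on the transcript
    end: int
    sequence: str
    tag_start: int  # 1-based position of the seeding tag within the candidate
    window: int
    arm_hypothesis: str  # "5p": tag on 5' arm (extended downstream), "3p": upstream


def excise_candidates(transcript: str, tag_position: int, tag_length: int,
                      windows: tuple[int, ...] = (80, 150, 250)) -> list[Candidate]:
    """Excise candidate precursors around a tag mapped at ``tag_position``.

    For each window size w, two candidates: tag on the 5' arm (extend w
    downstream) and tag on the 3' arm (extend w upstream), truncated at the
    transcript bounds.  Degenerate duplicates at the bounds are dropped.
    """
    n = len(transcript)
    tag_end = tag_position + tag_length - 1
    if tag_position < 1 or tag_end > n:
        log.warning("tag at %d (len %d) outside transcript of length %d",
                    tag_position, tag_length, n)
        return []
    out, seen = [], set()
    for w in windows:
        for arm in ("5p", "3p"):
            if arm == "5p":
                start, end = tag_position, min(n, tag_end + w)
            else:
                start, end = max(1, tag_position - w), tag_end
            if end - start + 1 <= tag_length:  # no room to fold anything
                continue
            key = (start, end)
            if key in seen:
                continue
            seen.add(key)
            out.append(Candidate(start, end, transcript[start - 1:end],
                                 tag_position - start + 1, w, arm))
    return out


def compute_mfei(mfe: float, length: int, gc_percent: float) -> tuple[float, float]:
    """AMFE = |MFE|/length*100 (kcal/mol per 100 nt); MFEI = AMFE/GC% (unitless)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_percent < 100:
        raise ValueError("gc_percent must be in (0, 100)")
    amfe = abs(mfe) / length * 100.0
    return amfe, amfe / gc_percent


def gc_percent(seq: str) -> float:
    seq = seq.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class PrecursorRecord:
    id: str
    sequence: str
    structure: str = ""
    mfe: float = 0.0
    amfe: float = 0.0
    mfei: float = 0.0
    gc: float = 0.0
    mature_span: tuple[int, int] = (0, 0)   # 1-based inclusive
    star_span: tuple[int, int] | None = None
    arm: str = ""


@dataclass
class HairpinValidation:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    paired_fraction: float = 0.0
    coverage_fraction: float = 0.0
    star_span: tuple[int, int] | None = None
    mfei: float = 0.0


def validate_hairpin(record: PrecursorRecord, fold_result: FoldResult,
                     reads: list[tuple[int, int]],
                     min_paired_frac: float = 0.75,
                     min_coverage_frac: float = 0.80,
                     coverage_window: int = 2,
                     max_bulge: int = 2,
                     min_mfei: float | None = None) -> HairpinValidation:
    """Validate a candidate miRNA hairpin.

    Pass requires (a) >= 75% of mature bases paired, (b) all mature pairing
    partners on one side outside the mature (the star arm; no pairing across
    the terminal loop) and forming a compact duplex — the star region may
    exceed the mature length by at most ``max_bulge`` nt, the usual plant
    annotation limit on asymmetric bulges, (c) >= 80% of precursor-mapped
    read counts starting within +-2 nt of the mature or star 5' ends; the
    MFEI is reported and only gated when ``min_mfei`` is set.  ``reads`` are
    (1-based 5' position, count).
    """
    reasons: list[str] = []
    partner = pair_table(fold_result.structure)
    ms, me = record.mature_span
    if not (1 <= ms <= me <= len(record.sequence)):
        raise ValueError(f"mature span {record.mature_span} outside precursor")
    mature_len = me - ms + 1
    partners = [partner[i - 1] for i in range(ms, me + 1) if partner[i - 1]]
    paired_frac = len(partners) / mature_len
    if paired_frac < min_paired_frac:
        reasons.append("low-duplex-pairing")
    # the star is the densest compact window of partners on a single side of
    # the mature; stray pairs elsewhere are tolerated up to the 75% rule
    width = mature_len + max_bulge
    best_window: list[int] = []
    for side in ([p for p in partners if p < ms], [p for p in partners if p > me]):
        side.sort()
        j = 0
        for i in range(len(side)):
            while side[i] - side[j] + 1 > width:
                j += 1
            if i - j + 1 > len(best_window):
                best_window = side[j:i + 1]
    duplex_frac = len(best_window) / mature_len
    derived_star = (best_window[0], best_window[-1]) if duplex_frac >= min_paired_frac else None
    if derived_star is None and paired_frac >= min_paired_frac:
        reasons.append("loop-spanning")  # paired, but not into one compact arm
    total = sum(c for _p, c in reads)
    if total == 0:
        reasons.append("no-coverage")
        cov_frac = 0.0
    else:
        anchors = [ms]
        if derived_star:
            anchors.append(derived_star[0])
        if record.star_span:
            anchors.append(record.star_span[0])
        near = sum(c for p, c in reads
                   if any(abs(p - a) <= coverage_window for a in anchors))
        cov_frac = near / total
        if cov_frac < min_coverage_frac:
            reasons.append("dispersed-reads")
    gc = record.gc or gc_percent(record.sequence)
    amfe, mfei = compute_mfei(fold_result.mfe, len(record.sequence), gc) \
        if 0 < gc < 100 else (0.0, 0.0)
    record.structure, record.mfe = fold_result.structure, fold_result.mfe
    record.amfe, record.mfei, record.gc = amfe, mfei, gc
    if record.star_span is None:
        record.star_span = derived_star
    if min_mfei is not None and mfei < min_mfei:
        reasons.append("low-mfei")
    return HairpinValidation(not reasons, reasons, paired_frac, cov_frac,
                             derived_star, mfei)


# ---------------------------------------------------------------------------
# Shuffle control
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(1000):
        # pick a random terminal edge per vertex; accept if they form a tree into `last`
        chosen = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices}
        ok = True
        for v in vertices:
            seen, u = {v}, v
            while u != last:
                u = chosen.get(u)
                if u is None or u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for ACGT sequences
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    shuffled: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in chosen:
            rest.remove(chosen[v])
        rng.shuffle(rest)
        shuffled[v] = rest + ([chosen[v]] if v in chosen else [])
    out = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)
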