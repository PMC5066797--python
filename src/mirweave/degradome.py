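"""Degradome-guided miRNA target calling.

Plant-style complementarity scoring over antiparallel miRNA:mRNA duplexes
(Watson-Crick 0, G:U wobble 0.5, mismatch 1, gap 2, penalties doubled at
miRNA positions 2-13 from the 5' end), exact-match degradome 5'-end profiles,
canonical cleavage-site arithmetic (the transcript base paired to miRNA
position 10), category 0-4 classification of the cleavage signature, and
t-plot data export.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import get_logger

log = get_logger(__name__)

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

#: per-position penalty for (miRNA base, target base): 0 Watson-Crick,
#: 0.5 G:U wobble, 1 mismatch
PENALTY = np.ones((4, 4))
for _a, _b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    PENALTY[_IDX[_a], _IDX[_b]] = 0.0
PENALTY[_IDX["G"], _IDX["T"]] = 0.5
PENALTY[_IDX["T"], _IDX["G"]] = 0.5

GAP_PENALTY = 2.0
SEED_REGION = (2, 13)  # inclusive miRNA positions with doubled penalties


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IDX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol in sequence: {exc}") from exc


def _mult(i: int) -> float:
    return 2.0 if SEED_REGION[0] <= i <= SEED_REGION[1] else 1.0


@dataclass
class AlignmentSite:
    """One miRNA:transcript duplex.  ``coords[i-1]`` is the 1-based transcript
    base paired to miRNA position i (None for a bulged miRNA base);
    ``states`` per miRNA position: '=' Watson-Crick, 'o' G:U, 'x' mismatch,
    '-' bulge."""

    mirna_id: str
    transcript_id: str
    t_start: int   # 1-based inclusive transcript interval of the duplex
    t_end: int
    score: float
    coords: list
    states: str


def align_mirna(mirna: str, transcript: str, max_score: float = 4.0,
                max_gap: int = 1, mirna_id: str = "", transcript_id: str = "") -> list[AlignmentSite]:
    """All duplexes with penalty score <= max_score, sorted by (score, position).

    The duplex is antiparallel: miRNA position 1 (5' end) pairs the 3'-most
    transcript base of the site.  At most one gap (a bulged base on either
    strand) is considered.
    """
    if not 18 <= len(mirna) <= 25:
        raise ValueError(f"miRNA must be 18-25 nt, got {len(mirna)}")
    m = _encode(mirna)
    L = len(m)
    if len(transcript) < L:
        return []
    t = _encode(transcript)
    mult = np.array([_mult(i) for i in range(1, L + 1)])
    sites: list[AlignmentSite] = []

    def pen_states(target_idx: np.ndarray) -> str:
        out = []
        for a, b in zip(m, target_idx):
            p = PENALTY[a, b]
            out.append("=" if p == 0 else ("o" if p == 0.5 else "x"))
        return "".join(out)

    # ungapped
    W = sliding_window_view(t, L)[:, ::-1]
    scores = (PENALTY[m[None, :], W] * mult).sum(axis=1)
    for s in np.flatnonzero(scores <= max_score):
        s = int(s)
        coords = [s + L - i + 1 for i in range(1, L + 1)]
        sites.append(AlignmentSite(mirna_id, transcript_id, s + 1, s + L,
                                   float(scores[s]), coords, pen_states(W[s])))

    if max_gap >= 1:
        # bulged transcript base between miRNA positions g and g+1
        if len(t) >= L + 1:
            Wb = sliding_window_view(t, L + 1)[:, ::-1]
            for g in range(1, L):
                cols = np.concatenate([np.arange(0, g), np.arange(g + 1, L + 1)])
                aligned = Wb[:, cols]
                gp = GAP_PENALTY * _mult(g + 1)
                sc = (PENALTY[m[None, :], aligned] * mult).sum(axis=1) + gp
                for s in np.flatnonzero(sc <= max_score):
                    s = int(s)
                    coords = [s + L + 1 - c for c in cols]
                    states = pen_states(aligned[s])
                    sites.append(AlignmentSite(mirna_id, transcript_id,
                                               s + 1, s + L + 1, float(sc[s]),
                                               coords, states))
        # bulged miRNA base at position g (unpaired; not at the ends)
        if len(t) >= L - 1:
            Wc = sliding_window_view(t, L - 1)[:, ::-1]
            keep = [i for i in range(1, L + 1)]
            for g in range(2, L):
                cols = [i - 1 if i < g else i - 2 for i in keep if i != g]
                aligned = Wc[:, cols]
                msub = np.delete(m, g - 1)
                multsub = np.delete(mult, g - 1)
                gp = GAP_PENALTY * _mult(g)
                sc = (PENALTY[msub[None, :], aligned] * multsub).sum(axis=1) + gp
                for s in np.flatnonzero(sc <= max_score):
                    s = int(s)
                    coords, states = [], []
                    ai = 0
                    for i in range(1, L + 1):
                        if i == g:
                            coords.append(None)
                            states.append("-")
                        else:
                            c = cols[ai]
                            coords.append(s + (L - 1) - c)
                            p = PENALTY[m[i - 1], aligned[s, ai]]
                            states.append("=" if p == 0 else ("o" if p == 0.5 else "x"))
                            ai += 1
                    sites.append(AlignmentSite(mirna_id, transcript_id,
                                               s + 1, s + L - 1, float(sc[s]),
                                               coords, "".join(states)))
    sites.sort(key=lambda a: (a.score, a.t_start, a.t_end))
    return sites


def canonical_cleavage_position(site: AlignmentSite) -> int | None:
    """Transcript base paired to miRNA position 10 (None if that position is
    a bulged miRNA base or falls outside the transcript)."""
    if len(site.coords) < 10:
        return None
    pos = site.coords[9]
    return int(pos) if pos is not None and pos >= 1 else None


# ---------------------------------------------------------------------------
# Degradome profiles
# ---------------------------------------------------------------------------

def map_degradome(tags: list[tuple[str, int]], transcripts: dict[str, str],
                  tag_lens: tuple[int, ...] = (20, 21)) -> dict[str, dict[int, int]]:
    """Exact sense-strand placement of degradome tags onto transcripts.

    ``tags`` are (sequence, count) with lengths restricted to ``tag_lens``
    (others are dropped with a log line).  Profile[pos] sums the counts of
    tags whose 5' end maps at the 1-based position; multi-mapping tags count
    at every exact locus.
    """
    profiles: dict[str, dict[int, int]] = {tid: {} for tid in transcripts}
    n_ok = n_mapped = 0
    for seq, count in tags:
        seq = seq.upper().replace("U", "T")
        if len(seq) not in tag_lens:
            continue
        n_ok += 1
        hit = False
        for tid, tseq in transcripts.items():
            start = tseq.find(seq)
            while start != -1:
                profiles[tid][start + 1] = profiles[tid].get(start + 1, 0) + count
                hit = True
                start = tseq.find(seq, start + 1)
        n_mapped += hit
    log.info("degradome mapping: %d/%d tags placed on the transcript set",
             n_mapped, n_ok)
    return {tid: prof for tid, prof in profiles.items() if prof}


def classify_category(count_at_site: int, profile: dict[int, int],
                      median_mode: str = "nonzero",
                      transcript_length: int | None = None) -> int:
    """Category 0-4 of a cleavage signature.

    4: only one raw read at the position; 0: count>1 equal to the unique
    transcript maximum; 1: count>1 equal to a tied maximum; 2: above the
    median; 3: at or below the median.  The median runs over positions
    carrying >=1 read (``median_mode='nonzero'``) or over every transcript
    position including zeros (``'all'``, needs ``transcript_length``).
    """
    if count_at_site < 1:
        raise ValueError("count_at_site must be >= 1")
    values = list(profile.values())
    if not values or count_at_site not in values:
        raise ValueError("site count not present in profile; build the profile first")
    if count_at_site == 1:
        return 4
    peak = max(values)
    if count_at_site == peak:
        return 0 if values.count(peak) == 1 else 1
    if median_mode == "nonzero":
        med = median(values)
    elif median_mode == "all":
        if transcript_length is None:
            raise ValueError("median_mode='all' requires transcript_length")
        med = median(values + [0] * (transcript_length - len(values)))
    else:
        raise ValueError(f"unknown median_mode {median_mode!r}")
    return 2 if count_at_site > med else 3


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    score: float
    cleavage_site: int   # 1-based transcript coordinate
    category: int
    peak_count: int


def call_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                 profiles: dict[str, dict[int, int]], max_score: float = 4.0,
                 max_gap: int = 1, cleave_window: int = 0,
                 median_mode: str = "nonzero") -> pd.DataFrame:
    """Emit a TargetHit per alignment site whose canonical cleavage position
    carries degradome signal (within +-cleave_window), with category 0-4.

    Columns mirror the published target-table schema: (small_rna, target,
    alignment_score, cleavage_site, category, peak_count), sorted by
    (miRNA, score, category); one best-scoring hit per cleavage site.
    """
    hits: dict[tuple, TargetHit] = {}
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            profile = profiles.get(tid)
            if not profile:
                continue
            for site in align_mirna(mseq, tseq, max_score, max_gap, mid, tid):
                pos = canonical_cleavage_position(site)
                if pos is None or pos > len(tseq):
                    continue
                window = [pos + d for d in range(-cleave_window, cleave_window + 1)]
                best = max((p for p in window if p in profile),
                           key=lambda p: profile[p], default=None)
                if best is None:
                    continue
                cat = classify_category(profile[best], profile, median_mode,
                                        transcript_length=len(tseq))
                key = (mid, tid, best)
                if key not in hits or site.score < hits[key].score:
                    hits[key] = TargetHit(mid, tid, site.score, best, cat,
                                          profile[best])
    rows = [{"small_rna": h.mirna_id, "target": h.transcript_id,
             "alignment_score": h.score, "cleavage_site": h.cleavage_site,
             "category": h.category, "peak_count": h.peak_count}
            for h in hits.values()]
    df = pd.DataFrame(rows, columns=["small_rna", "target", "alignment_score",
                                     "cleavage_site", "category", "peak_count"])
    return df.sort_values(["small_rna", "alignment_score", "category", "target"],
                          kind="mergesort").reset_index(drop=True)


def tplot_data(cleavage_site: int, profile: dict[int, int]) -> pd.DataFrame:
    """Per-position table (position, count, is_cleavage_site) for a t-plot."""
    rows = [{"position": p, "count": c, "is_cleavage_site": p == cleavage_site}
            for p, c in sorted(profile.items())]
    return pd.DataFrame(rows, columns=["position", "count", "is_cleavage_site"])
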