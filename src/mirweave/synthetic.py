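"""Synthetic study generator with planted ground truth.

Emulates an eight-time-point heavy-metal stress experiment on a plant without
a reference genome: a transcript set standing in for assembled unigenes,
collapsed small-RNA tag libraries S1..S8 whose background length histogram
peaks at 24 nt, hairpin precursors that yield mature/star read stacks, a
degradome library of 20-21-nt tags peaking at the canonical cleavage site,
negative-binomial count trajectories with planted up/down regulation and
anti-correlated miRNA-target pairs, and block-correlated gene sets with
planted hub genes.  Every planted feature is recorded in a machine-readable
truth manifest so each downstream stage can be scored against ground truth.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import get_logger, write_fasta, write_tag_fasta, write_tsv

log = get_logger(__name__)

BASES = "ACGT"
_COMP = str.maketrans("ACGTU", "TGCAA")

#: background tag length law: 18..25 nt with a pronounced 24-nt mode, the
#: signature of a plant small-RNA population dominated by 24-nt siRNAs
BACKGROUND_LENGTHS = np.arange(18, 26)
BACKGROUND_LENGTH_PROBS = np.array([0.06, 0.06, 0.08, 0.14, 0.08, 0.08, 0.40, 0.10])


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    """Machine-readable record of everything the generator planted."""

    planted_mirnas: list = field(default_factory=list)        # (id, mature, precursor id, arm)
    planted_interactions: list = field(default_factory=list)  # (mirna id, transcript id, cleavage pos, peak count)
    planted_de: list = field(default_factory=list)            # (feature id, direction, trajectory)
    planted_pairs: list = field(default_factory=list)         # (mirna id, target id, correlation sign)
    planted_modules: dict = field(default_factory=dict)       # gene id -> block label
    planted_hubs: list = field(default_factory=list)
    planted_hairpins: dict = field(default_factory=dict)      # precursor id -> spans/arm record
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def validate_manifest(manifest: TruthManifest, transcripts: dict[str, str],
                      counts: pd.DataFrame) -> list[str]:
    """Return a list of consistency problems (empty = truth-consistent)."""
    problems = []
    mirna_ids = {m[0] for m in manifest.planted_mirnas}
    for mid, mature, pre_id, arm in manifest.planted_mirnas:
        if pre_id not in transcripts:
            problems.append(f"precursor {pre_id} of {mid} missing from transcripts")
        elif mature not in transcripts[pre_id]:
            problems.append(f"mature of {mid} absent from precursor {pre_id}")
    for mid, tid, pos, peak in manifest.planted_interactions:
        if mid not in mirna_ids:
            problems.append(f"interaction miRNA {mid} not planted")
        if tid not in transcripts:
            problems.append(f"interaction transcript {tid} missing")
        elif not 1 <= pos <= len(transcripts[tid]):
            problems.append(f"cleavage position {pos} outside {tid}")
    for fid, _direction, _traj in manifest.planted_de:
        # DE features are either genes (rows of counts) or planted miRNAs
        if fid not in counts.index and fid not in mirna_ids:
            problems.append(f"planted DE feature {fid} missing from counts")
    for gid in list(manifest.planted_modules) + list(manifest.planted_hubs):
        if gid not in counts.index:
            problems.append(f"coexpression gene {gid} missing from counts")
    return problems


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def gen_transcriptome(n: int, length_range: tuple[int, int] = (500, 1500),
                      gc: float = 0.45, seed: int = 0,
                      prefix: str = "TR") -> dict[str, str]:
    """Generate ``n`` random transcripts with uniform lengths and target GC."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    lo, hi = length_range
    if lo < 200 or hi < lo:
        raise ValueError(f"invalid length range {length_range}; min length >= 200")
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out[f"{prefix}{i + 1:05d}"] = _random_seq(rng, length, gc)
    return out


# ---------------------------------------------------------------------------
# Hairpin planting
# ---------------------------------------------------------------------------

def plant_hairpin(mature: str, loop_len: int = 15, flank_len: int = 15,
                  wobble_count: int = 0, seed: int = 0,
                  arm: str = "5p") -> tuple[str, dict]:
    """Build a precursor around ``mature`` with a near-complementary star arm.

    The precursor is 5'flank + mature + loop + star-core + 3'flank (arm="5p")
    or the arm-swapped layout (arm="3p"); the star core is the reverse
    complement of the mature with up to ``wobble_count`` positions turned into
    G:U wobbles.  The star span recorded in the truth dictionary is the
    opposite-arm segment shifted 2 nt toward its own 3' end (canonical Dicer
    2-nt 3' overhang).
    """
    mature = mature.upper().replace("U", "T")
    if not set(mature) <= set(BASES):
        raise ValueError(f"mature contains non-ACGU symbols: {mature}")
    if not 20 <= len(mature) <= 24:
        raise ValueError(f"mature length must be 20-24 nt, got {len(mature)}")
    if wobble_count > 3:
        raise ValueError("wobble_count must be <= 3")
    if flank_len < 2:
        raise ValueError("flank_len must be >= 2 (star 3' overhang needs flank)")
    rng = np.random.default_rng(seed)
    L = len(mature)
    star_core = list(revcomp(mature))
    # G:U wobbles: mature G pairs star U (C->T) or mature T pairs star G (A->G)
    eligible = [i for i, b in enumerate(mature) if b in "GT"]
    n_wob = min(wobble_count, len(eligible))
    if n_wob < wobble_count:
        log.warning("only %d wobble-eligible positions for %d requested", n_wob, wobble_count)
    for i in rng.choice(eligible, size=n_wob, replace=False) if n_wob else []:
        j = L - 1 - int(i)  # star-core index pairing mature position i
        star_core[j] = "T" if mature[int(i)] == "G" else "G"
    star_core = "".join(star_core)
    flank5 = _random_seq(rng, flank_len)
    loop = _random_seq(rng, loop_len)
    flank3 = _random_seq(rng, flank_len)
    if arm == "5p":
        precursor = flank5 + mature + loop + star_core + flank3
        mature_span = (flank_len + 1, flank_len + L)
        s0 = flank_len + L + loop_len  # 0-based offset of star core
        star_span = (s0 + 3, s0 + L + 2)
    elif arm == "3p":
        precursor = flank5 + star_core + loop + mature + flank3
        mature_span = (flank_len + L + loop_len + 1, flank_len + L + loop_len + L)
        # opposite arm is 5'-side; its 3' end points toward the loop
        star_span = (flank_len + 3, flank_len + L + 2)
    else:
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    truth = {"mature_span": mature_span, "star_span": star_span, "arm": arm,
             "star_seq": precursor[star_span[0] - 1:star_span[1]]}
    return precursor, truth


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def simulate_counts(features: list[str], base_mean: float | dict = 100.0,
                    dispersion: float = 0.1, de_plan: dict | None = None,
                    n_samples: int = 8, seed: int = 0) -> pd.DataFrame:
    """Negative-binomial counts over S1..Sk with planted fold trajectories.

    ``de_plan`` maps feature id -> per-sample fold multipliers; dispersion 0
    degenerates to Poisson (var = mean).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    de_plan = de_plan or {}
    unknown = set(de_plan) - set(features)
    if unknown:
        raise ValueError(f"de_plan features not in feature list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    means = np.empty((len(features), n_samples))
    for i, fid in enumerate(features):
        base = base_mean[fid] if isinstance(base_mean, dict) else base_mean
        if base <= 0:
            raise ValueError("base_mean must be > 0")
        traj = np.asarray(de_plan.get(fid, np.ones(n_samples)), dtype=float)
        if traj.shape != (n_samples,):
            raise ValueError(f"trajectory for {fid} must have {n_samples} entries")
        means[i] = base * traj
    if dispersion == 0:
        counts = rng.poisson(means)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + means))
    return pd.DataFrame(counts, index=pd.Index(features, name="feature"), columns=samples)


# ---------------------------------------------------------------------------
# Degradome simulation
# ---------------------------------------------------------------------------

def simulate_degradome(interactions: list, transcripts: dict[str, str],
                       peak_count: int = 5, background_rate: float = 0.05,
                       tag_lens: tuple[int, ...] = (20, 21),
                       seed: int = 0) -> list[tuple[str, str, int, str, int]]:
    """Degradome tags: a peak at each planted cleavage site plus sparse count-1
    background at uniform random positions.

    Returns (tag id, sequence, count, transcript of origin, 1-based 5' position)
    records; ``background_rate`` is expected background tags per kb.
    """
    if peak_count <= 1:
        raise ValueError("peak_count must exceed the background maximum of 1")
    rng = np.random.default_rng(seed)
    records = []
    n = 0
    for mid, tid, pos, peak in [(i[0], i[1], i[2], i[3] if len(i) > 3 else peak_count)
                                for i in interactions]:
        seq = transcripts[tid]
        tlen = int(rng.choice(tag_lens))
        if pos - 1 + tlen > len(seq):
            log.warning("cleavage site %d on %s too close to 3' end; skipped", pos, tid)
            continue
        n += 1
        records.append((f"DT{n:06d}", seq[pos - 1:pos - 1 + tlen], int(peak), tid, pos))
    for tid, seq in transcripts.items():
        n_bg = rng.poisson(background_rate * len(seq) / 1000.0)
        max_tlen = max(tag_lens)
        for _ in range(n_bg):
            if len(seq) <= max_tlen:
                continue
            pos = int(rng.integers(1, len(seq) - max_tlen + 1))
            tlen = int(rng.choice(tag_lens))
            n += 1
            records.append((f"DT{n:06d}", seq[pos - 1:pos - 1 + tlen], 1, tid, pos))
    return records


# ---------------------------------------------------------------------------
# Coexpression blocks
# ---------------------------------------------------------------------------

def gen_coexpression_blocks(n_blocks: int = 4, block_size: int = 100,
                            n_samples: int = 8, intra_cor: float = 0.8,
                            hub_cor: float = 1.0, seed: int = 0,
                            prefix: str = "CXG"):
    """Planted-partition expression profiles with one hub gene per block.

    Each gene is loading*factor + noise with loading sqrt(intra_cor), so the
    gene-gene correlation within a block is ``intra_cor`` (up to noise-noise
    overlap).  Block factors are mean-centred and sample-orthogonalised (QR),
    and each gene's noise vector is projected orthogonal to every factor, so
    the planted partition is realised exactly in the emitted sample: expected
    inter-block correlation is zero with only pure noise-noise overlap on
    top.  The hub gene's profile mixes the factor at weight ``hub_cor``
    (default 1.0: a noise-free copy, which makes it the best-connected member
    of its block even at small sample counts).

    Returns (profiles DataFrame genes x samples, labels dict, hub ids).
    """
    if not 0 < intra_cor < 1:
        raise ValueError("intra_cor must be in (0,1)")
    rng = np.random.default_rng(seed)
    if n_samples <= n_blocks + 1:
        raise ValueError("need at least n_blocks + 2 samples for orthogonal factors")
    raw = rng.standard_normal((n_samples, n_blocks))
    raw -= raw.mean(axis=0)                      # mean-zero columns
    Q, _ = np.linalg.qr(raw)                     # orthonormal, still mean-zero
    factors = Q * np.sqrt(n_samples - 1)         # unit sample variance (ddof=1)
    a, b = np.sqrt(intra_cor), np.sqrt(1 - intra_cor)

    def noise() -> np.ndarray:
        e = rng.standard_normal(n_samples)
        e -= e.mean()
        e -= Q @ (Q.T @ e)                       # orthogonal to every factor
        sd = e.std(ddof=1)
        if sd == 0:  # pragma: no cover - degenerate draw
            return noise()
        return e / sd

    rows, ids, labels, hubs = [], [], {}, []
    for blk in range(n_blocks):
        label = f"block{blk + 1}"
        f = factors[:, blk]
        for g in range(block_size):
            gid = f"{prefix}{blk + 1:02d}_{g + 1:03d}"
            if g == 0:
                prof = hub_cor * f + np.sqrt(max(0.0, 1 - hub_cor ** 2)) * noise()
                hubs.append(gid)
            else:
                prof = a * f + b * noise()
            rows.append(prof)
            ids.append(gid)
            labels[gid] = label
    samples = [f"S{i + 1}" for i in range(n_samples)]
    return pd.DataFrame(rows, index=pd.Index(ids, name="feature"), columns=samples), labels, hubs


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Default synthetic study conditions (eight stress durations S1..S8)."""

    n_samples: int = 8
    n_mirnas: int = 30
    n_interactions: int = 30
    n_decoys: int = 30
    n_null_genes: int = 200
    n_background_tags: int = 300
    n_contaminant_tags: int = 20
    n_contaminants: int = 10
    mirna_len: int = 21
    transcript_length_range: tuple[int, int] = (500, 1500)
    gc: float = 0.45
    loop_len: int = 15
    flank_len: int = 15
    mirna_base_mean: float = 100.0
    gene_base_mean: float = 200.0
    dispersion: float = 0.05
    fold_change: float = 8.0
    n_anticorr: int = 20          # planted negatively-correlated miRNA-target pairs
    peak_count: int = 5
    background_rate: float = 0.05  # degradome background tags per kb
    coexpr_blocks: int = 4
    coexpr_block_size: int = 100
    intra_cor: float = 0.8
    hub_cor: float = 1.0
    coexpr_amplitude: float = 1.5  # log2-fold swing applied to block profiles


@dataclass
class StudyData:
    design: StudyDesign
    manifest: TruthManifest
    transcripts: dict[str, str]          # targets + decoys + precursors
    mirnas: dict[str, str]               # reference matures (stand-in miRBase)
    srna_libraries: list[list[tuple[str, str, int]]]   # per library: (id, seq, count)
    degradome: list[tuple[str, str, int, str, int]]
    counts: pd.DataFrame                 # all features x S1..Sk (raw counts)
    lengths: pd.Series
    contaminants: dict[str, str]
    gene2term: pd.DataFrame
    mirna_counts: pd.DataFrame           # per-miRNA planted tag counts (truth side)


def _step_trajectory(direction: str, fold: float, n: int) -> list[float]:
    half = n // 2
    up = [1.0] * half + [fold] * (n - half)
    return up if direction == "up" else up[::-1]


def simulate_study(design: StudyDesign | None = None, seed: int = 0,
                   outdir: str | Path | None = None) -> StudyData:
    """Generate the complete synthetic experiment; optionally write all files."""
    d = design or StudyDesign()
    rng = np.random.default_rng(seed)
    k = d.n_samples
    manifest = TruthManifest(seed=seed)

    # --- miRNAs and their precursors -------------------------------------
    mirnas: dict[str, str] = {}
    while len(mirnas) < d.n_mirnas:
        mid = f"sal-miR{1001 + len(mirnas)}"
        seq = _random_seq(rng, d.mirna_len, 0.5)
        if seq not in mirnas.values():
            mirnas[mid] = seq
    transcripts: dict[str, str] = {}
    star_seqs: dict[str, str] = {}
    for i, (mid, mature) in enumerate(mirnas.items()):
        arm = "5p" if i % 2 == 0 else "3p"
        pre_id = f"PRE{i + 1:03d}"
        pre, truth = plant_hairpin(mature, d.loop_len, d.flank_len,
                                   wobble_count=int(rng.integers(0, 3)),
                                   seed=int(rng.integers(2 ** 31)), arm=arm)
        transcripts[pre_id] = pre
        star_seqs[mid] = truth["star_seq"]
        manifest.planted_mirnas.append((mid, mature, pre_id, arm))
        manifest.planted_hairpins[pre_id] = {**truth, "mirna": mid}

    # --- target and decoy transcripts ------------------------------------
    targets = gen_transcriptome(d.n_interactions, d.transcript_length_range,
                                d.gc, seed=int(rng.integers(2 ** 31)), prefix="TGT")
    decoys = gen_transcriptome(d.n_decoys, d.transcript_length_range,
                               d.gc, seed=int(rng.integers(2 ** 31)), prefix="DCY")
    mirna_ids = list(mirnas)
    for j, tid in enumerate(targets):
        mid = mirna_ids[j % len(mirna_ids)]
        site = revcomp(mirnas[mid])
        L = len(site)
        seq = targets[tid]
        s = int(rng.integers(50, len(seq) - L - 50))  # 1-based embed start
        targets[tid] = seq[:s - 1] + site + seq[s - 1 + L:]
        cleavage = s + L - 10  # transcript base paired to miRNA position 10
        manifest.planted_interactions.append((mid, tid, cleavage, d.peak_count))
    transcripts.update(targets)
    transcripts.update(decoys)

    # --- expression plans: anti-correlated and positive pairs -------------
    mirna_plan: dict[str, list[float]] = {}
    gene_plan: dict[str, list[float]] = {}
    for j, (mid, tid, _pos, _peak) in enumerate(manifest.planted_interactions):
        if mid in mirna_plan:  # keep the direction already planted for this miRNA
            m_dir = "up" if mirna_plan[mid][-1] > mirna_plan[mid][0] else "down"
        else:
            m_dir = "up" if j % 2 == 0 else "down"
        if j < d.n_anticorr:
            g_dir = "down" if m_dir == "up" else "up"
            sign = -1
        else:
            g_dir = m_dir
            sign = 1
        if mid not in mirna_plan:  # a miRNA may target several transcripts
            mirna_plan[mid] = _step_trajectory(m_dir, d.fold_change, k)
            manifest.planted_de.append((mid, m_dir, mirna_plan[mid]))
        gene_plan[tid] = _step_trajectory(g_dir, d.fold_change, k)
        manifest.planted_de.append((tid, g_dir, gene_plan[tid]))
        manifest.planted_pairs.append((mid, tid, sign))

    # --- small-RNA libraries ----------------------------------------------
    mirna_counts = simulate_counts(list(mirnas), d.mirna_base_mean, d.dispersion,
                                   de_plan=mirna_plan, n_samples=k,
                                   seed=int(rng.integers(2 ** 31)))
    star_counts = simulate_counts([f"{m}*" for m in mirnas], 10.0, d.dispersion,
                                  n_samples=k, seed=int(rng.integers(2 ** 31)))
    contaminants = gen_transcriptome(d.n_contaminants, (200, 300), 0.5,
                                     seed=int(rng.integers(2 ** 31)), prefix="rRNA")
    libraries: list[list[tuple[str, str, int]]] = [[] for _ in range(k)]
    for s in range(k):
        for mi, (mid, mature) in enumerate(mirnas.items()):
            c = int(mirna_counts.iloc[mi, s])
            if c > 0:
                libraries[s].append((f"{mid}_m", mature, c))
            cs = int(star_counts.iloc[mi, s])
            if cs > 0:
                libraries[s].append((f"{mid}_star", star_seqs[mid], cs))
    bg_seqs = set()
    for b in range(d.n_background_tags):
        length = int(rng.choice(BACKGROUND_LENGTHS, p=BACKGROUND_LENGTH_PROBS))
        seq = _random_seq(rng, length, 0.5)
        if seq in bg_seqs or seq in mirnas.values():
            continue
        bg_seqs.add(seq)
        for s in rng.choice(k, size=int(rng.integers(1, 4)), replace=False):
            libraries[int(s)].append((f"bg{b + 1:04d}", seq, int(rng.integers(1, 4))))
    cont_ids = list(contaminants)
    for c in range(d.n_contaminant_tags):
        src = contaminants[cont_ids[int(rng.integers(len(cont_ids)))]]
        length = int(rng.integers(18, 25))
        start = int(rng.integers(0, len(src) - length))
        seq = src[start:start + length]
        s = int(rng.integers(k))
        libraries[s].append((f"cont{c + 1:03d}", seq, int(rng.integers(1, 5))))

    # --- degradome ---------------------------------------------------------
    degradome = simulate_degradome(manifest.planted_interactions, transcripts,
                                   peak_count=d.peak_count,
                                   background_rate=d.background_rate,
                                   seed=int(rng.integers(2 ** 31)))

    # --- gene counts (targets, decoys, precursors, nulls, coexpr blocks) ---
    coexpr, labels, hubs = gen_coexpression_blocks(
        d.coexpr_blocks, d.coexpr_block_size, k, d.intra_cor, d.hub_cor,
        seed=int(rng.integers(2 ** 31)))
    manifest.planted_modules = labels
    manifest.planted_hubs = hubs
    null_ids = [f"NUL{i + 1:04d}" for i in range(d.n_null_genes)]
    base_features = list(targets) + list(decoys) + \
        [t for t in transcripts if t.startswith("PRE")] + null_ids
    counts_base = simulate_counts(base_features, d.gene_base_mean, d.dispersion,
                                  de_plan=gene_plan, n_samples=k,
                                  seed=int(rng.integers(2 ** 31)))
    block_means = d.gene_base_mean * np.power(2.0, d.coexpr_amplitude * coexpr.to_numpy())
    r = 1.0 / d.dispersion
    block_counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + block_means)),
        index=coexpr.index, columns=coexpr.columns)
    counts = pd.concat([counts_base, block_counts])
    lengths = pd.Series({fid: len(transcripts[fid]) if fid in transcripts
                         else int(rng.integers(*d.transcript_length_range))
                         for fid in counts.index}, name="length")

    # --- gene -> term annotation ------------------------------------------
    terms = [f"T{i + 1:04d}" for i in range(30)]
    term_names = {t: f"process {t}" for t in terms}
    term_names["T0001"] = "metal ion transport"
    rows = []
    for gid in counts.index:
        assigned = set(rng.choice(terms[1:], size=int(rng.integers(1, 4)), replace=False))
        if gid in targets:
            assigned.add("T0001")
        for t in sorted(assigned):
            rows.append((gid, t, term_names[t]))
    gene2term = pd.DataFrame(rows, columns=["gene", "term", "name"])

    data = StudyData(d, manifest, transcripts, mirnas, libraries, degradome,
                     counts, lengths, contaminants, gene2term, mirna_counts)
    if outdir is not None:
        write_study(data, outdir)
    return data


def write_study(data: StudyData, outdir: str | Path) -> None:
    """Write every input file the pipeline stages read, plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "transcripts.fa", data.transcripts)
    write_fasta(outdir / "reference_mirnas.fa", data.mirnas)
    write_fasta(outdir / "contaminants.fa", data.contaminants)
    for s, lib in enumerate(data.srna_libraries):
        write_tag_fasta(outdir / f"srna_S{s + 1}.fa", lib)
    write_tag_fasta(outdir / "degradome.fa",
                    [(tid, seq, count) for tid, seq, count, _src, _pos in data.degradome])
    counts = data.counts.copy()
    counts.insert(0, "length", data.lengths)
    write_tsv(counts.reset_index(), outdir / "counts.tsv")
    write_tsv(data.gene2term, outdir / "gene2term.tsv")
    data.manifest.to_json(outdir / "truth_manifest.json")
    log.info("synthetic study written to %s (seed=%d)", outdir, data.manifest.seed)
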