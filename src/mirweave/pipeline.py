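"""File-based pipeline stages and the end-to-end runner.

Stage order: simulate? -> srna -> hairpin -> degradome -> de -> integrate ->
network.  Every stage reads its inputs from and writes plain TSV/FASTA/JSON
outputs into the configured output directory; reruns with an identical
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import degradome as deg
from . import hairpin as hp
from . import integrate as integ
from . import network as net
from .expression import Thresholds, call_de_mirna, call_deg, zscore
from .io import (PipelineConfig, get_logger, read_fasta, read_tag_fasta,
                 read_tsv, sha256_file, write_json, write_tsv)
from .synthetic import StudyDesign, simulate_study, validate_manifest

log = get_logger(__name__)


def _thresholds(cfg: PipelineConfig) -> Thresholds:
    return Thresholds(gene_p=cfg.gene_p, gene_fdr=cfg.gene_fdr,
                      gene_lfc=cfg.gene_lfc, mirna_p=cfg.mirna_p,
                      mirna_abundance=cfg.mirna_abundance,
                      network_power=cfg.network_power,
                      score_cutoff=cfg.max_score,
                      corr_negative=cfg.corr_negative)


def _read_counts(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.Series]:
    df = read_tsv(cfg.path(cfg.counts)).set_index("feature")
    lengths = df.pop("length")
    return df, lengths


def _srna_library_paths(cfg: PipelineConfig) -> list[Path]:
    outdir = Path(cfg.outdir)
    paths = sorted(outdir.glob(f"{cfg.srna_prefix}S*.fa"),
                   key=lambda p: int(p.stem.split("S")[-1]))
    if not paths:
        raise FileNotFoundError(f"no {cfg.srna_prefix}S*.fa libraries in {outdir}")
    return paths


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig):
    design = StudyDesign(**cfg.simulate_params)
    log.info("simulate: seed=%d", cfg.seed)
    data = simulate_study(design, seed=cfg.seed, outdir=cfg.outdir)
    problems = validate_manifest(data.manifest, data.transcripts, data.counts)
    if problems:
        raise RuntimeError(f"truth manifest inconsistent: {problems}")
    return data


def stage_srna(cfg: PipelineConfig) -> pd.DataFrame:
    libs = []
    for path in _srna_library_paths(cfg):
        libs.append([(seq, count) for _name, seq, count in read_tag_fasta(path)])
    catalog = cat.collapse_reads(libs)
    catalog = cat.filter_by_length(catalog, cfg.min_len, cfg.max_len)
    contaminants = read_fasta(cfg.path(cfg.contaminants))
    catalog, removed = cat.remove_contaminants(catalog, contaminants)
    log.info("srna: %d tags kept, %d contaminant tags removed (seed=%d)",
             len(catalog), len(removed), cfg.seed)
    reference = read_fasta(cfg.path(cfg.reference_mirnas))
    matches = cat.match_known(catalog, reference, cfg.max_sub, cfg.max_shift)
    table = cat.catalog_table(catalog, matches)
    write_tsv(table, cfg.path("catalog.tsv"))
    hist = cat.length_distribution(catalog, cfg.min_len, cfg.max_len)
    write_tsv(hist.reset_index(), cfg.path("length_distribution.tsv"))
    return table


def stage_hairpin(cfg: PipelineConfig) -> pd.DataFrame:
    """Excise and validate candidate precursors around catalogued tags."""
    transcripts = read_fasta(cfg.path(cfg.transcripts))
    table = read_tsv(cfg.path("catalog.tsv"))
    engine = hp.default_engine()
    rows = []
    precursor_seqs = {}
    n_pre = 0
    # positions of every catalogued tag on every transcript (exact matches)
    tag_rows = list(table.itertuples(index=False))
    for tid, tseq in transcripts.items():
        located = []  # (tag, position, total)
        for row in tag_rows:
            start = tseq.find(row.tag)
            while start != -1:
                located.append((row.tag, start + 1, int(row.total)))
                start = tseq.find(row.tag, start + 1)
        if not located:
            continue
        located.sort(key=lambda x: (-x[2], x[1]))
        for tag, pos, total in located[:4]:  # seed from the most abundant tags
            best = None
            for cand in hp.excise_candidates(tseq, pos, len(tag), tuple(cfg.windows)):
                fr = hp.fold(cand.sequence, engine)
                reads = [(p - cand.start + 1, t) for tg, p, t in located
                         if cand.start <= p <= cand.end - len(tg) + 1]
                record = hp.PrecursorRecord(
                    id="", sequence=cand.sequence,
                    mature_span=(cand.tag_start, cand.tag_start + len(tag) - 1),
                    arm=cand.arm_hypothesis)
                result = hp.validate_hairpin(record, fr, reads,
                                             min_mfei=cfg.min_mfei)
                key = (result.passed, result.paired_fraction)
                if best is None or key > best[0]:
                    best = (key, cand, record, result)
            if best is None:
                continue
            _key, cand, record, result = best
            n_pre += 1
            pre_id = f"hp{n_pre:04d}"
            precursor_seqs[pre_id] = record.sequence
            rows.append({
                "precursor": pre_id, "transcript": tid, "tag": tag,
                "start": cand.start, "end": cand.end,
                "mfe": round(record.mfe, 2), "amfe": round(record.amfe, 3),
                "mfei": round(record.mfei, 4), "gc": round(record.gc, 2),
                "mature_start": record.mature_span[0],
                "mature_end": record.mature_span[1],
                "star_start": record.star_span[0] if record.star_span else 0,
                "star_end": record.star_span[1] if record.star_span else 0,
                "structure": record.structure,
                "passed": result.passed, "reasons": ";".join(result.reasons),
            })
            if result.passed:
                break  # one validated precursor per transcript is enough
    df = pd.DataFrame(rows, columns=[
        "precursor", "transcript", "tag", "start", "end", "mfe", "amfe",
        "mfei", "gc", "mature_start", "mature_end", "star_start", "star_end",
        "structure", "passed", "reasons"])
    write_tsv(df, cfg.path("precursors.tsv"))
    from .io import write_fasta
    write_fasta(cfg.path("precursors.fa"), precursor_seqs)
    log.info("hairpin: %d candidates, %d passed (seed=%d)", len(df),
             int(df["passed"].sum()) if len(df) else 0, cfg.seed)
    return df


def stage_degradome(cfg: PipelineConfig) -> pd.DataFrame:
    transcripts = read_fasta(cfg.path(cfg.transcripts))
    mirnas = read_fasta(cfg.path(cfg.reference_mirnas))
    tags = [(seq, count) for _name, seq, count in
            read_tag_fasta(cfg.path(cfg.degradome))]
    profiles = deg.map_degradome(tags, transcripts)
    hits = deg.call_targets(mirnas, transcripts, profiles,
                            max_score=cfg.max_score, max_gap=cfg.max_gap,
                            cleave_window=cfg.cleave_window,
                            median_mode=cfg.median_mode)
    write_tsv(hits, cfg.path("targets.tsv"))
    tdir = cfg.path("tplots")
    tdir.mkdir(exist_ok=True)
    for _i, h in hits.iterrows():
        tp = deg.tplot_data(int(h["cleavage_site"]), profiles[h["target"]])
        write_tsv(tp, tdir / f"{h['small_rna']}__{h['target']}.tsv")
    log.info("degradome: %d target hits (seed=%d)", len(hits), cfg.seed)
    return hits


def stage_de(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    th = _thresholds(cfg)
    counts, lengths = _read_counts(cfg)
    de_genes = call_deg(counts, lengths, cfg.control, th)
    write_tsv(de_genes, cfg.path("de_genes.tsv"))
    # per-reference aggregated miRNA counts from the catalog
    table = read_tsv(cfg.path("catalog.tsv"))
    sample_cols = [c for c in table.columns if c.startswith("S") and c[1:].isdigit()]
    matched = table[table["ref_id"].astype(str) != ""].dropna(subset=["ref_id"])
    mirna_counts = matched.groupby("ref_id")[sample_cols].sum()
    mirna_counts.index.name = "feature"
    de_mirnas, updown = call_de_mirna(mirna_counts, cfg.control, th)
    write_tsv(de_mirnas, cfg.path("de_mirnas.tsv"))
    write_tsv(updown, cfg.path("updown_by_timepoint.tsv"))
    write_tsv(mirna_counts.reset_index(), cfg.path("mirna_counts.tsv"))
    write_tsv(zscore(counts).reset_index(), cfg.path("zscores.tsv"))
    log.info("de: %d significant gene flags, %d strict DE miRNAs (seed=%d)",
             int(de_genes["significant"].sum()), int(de_mirnas["strict"].sum()),
             cfg.seed)
    return de_genes, de_mirnas


def stage_integrate(cfg: PipelineConfig) -> pd.DataFrame:
    de_genes = read_tsv(cfg.path("de_genes.tsv"))
    de_mirnas = read_tsv(cfg.path("de_mirnas.tsv"))
    hits = read_tsv(cfg.path("targets.tsv"))
    counts, _lengths = _read_counts(cfg)
    mirna_counts = read_tsv(cfg.path("mirna_counts.tsv")).set_index("feature")
    pairs = integ.pair_de(de_mirnas, hits, de_genes)
    pairs = integ.correlate_pairs(pairs, mirna_counts[list(counts.columns)],
                                  counts, negative_threshold=cfg.corr_negative)
    write_tsv(pairs, cfg.path("pairs.tsv"))
    g2t = read_tsv(cfg.path(cfg.gene2term))
    background = set(g2t["gene"])
    selected = set(pairs["target"]) & background
    enrichment = integ.term_enrichment(selected, background, g2t) if selected \
        else pd.DataFrame()
    write_tsv(enrichment, cfg.path("enrichment.tsv"))
    log.info("integrate: %d DE pairs, %d negative (seed=%d)", len(pairs),
             int((pairs["direction"] == "negative").sum()) if len(pairs) else 0,
             cfg.seed)
    return pairs


def stage_network(cfg: PipelineConfig) -> pd.Series:
    counts, _lengths = _read_counts(cfg)
    expr = net.filter_genes(counts, cfg.max_zeros)
    adj = net.adjacency(expr, cfg.network_power, cfg.signed)
    tom = net.tom_similarity(adj)
    modules = net.detect_modules(tom, cfg.min_module, cfg.cut_height)
    conn = net.connectivity(adj)
    kin = net.intramodular_connectivity(adj, modules)
    mod_df = pd.DataFrame({"gene": modules.index, "module": modules.to_numpy(),
                           "connectivity": conn.round(4).to_numpy(),
                           "intramodular_connectivity": kin.round(4).to_numpy()})
    write_tsv(mod_df, cfg.path("modules.tsv"))
    eig = net.module_eigengenes(expr, modules)
    write_tsv(eig.round(6).reset_index(), cfg.path("eigengenes.tsv"))
    hubs = cfg.hubs or list(kin.sort_values(ascending=False).index[:2])
    edges, shared = net.hub_subnetwork(adj, hubs, cfg.edge_threshold)
    edges["weight"] = edges["weight"].round(6)
    write_tsv(edges, cfg.path("edges.tsv"))
    write_json({"hubs": hubs, "shared_neighbours": sorted(shared)},
               cfg.path("hub_summary.json"))
    log.info("network: %d modules, hubs %s (seed=%d)",
             modules[modules != net.GREY].nunique(), hubs, cfg.seed)
    return modules


STAGES = {
    "simulate": stage_simulate,
    "srna": stage_srna,
    "hairpin": stage_hairpin,
    "degradome": stage_degradome,
    "de": stage_de,
    "integrate": stage_integrate,
    "network": stage_network,
}
STAGE_ORDER = ["simulate", "srna", "hairpin", "degradome", "de", "integrate",
               "network"]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages in order; returns the output directory.

    A failing stage aborts with its name; partial outputs are retained.  The
    run manifest records parameters, the seed and input checksums.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for name in STAGE_ORDER:
        if name not in cfg.stages:
            continue
        try:
            STAGES[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    checksums = {}
    for fname in (cfg.transcripts, cfg.degradome, cfg.counts,
                  cfg.reference_mirnas, cfg.contaminants, cfg.gene2term):
        p = cfg.path(fname)
        if p.exists():
            checksums[p.name] = sha256_file(p)
    write_json({"config": dataclasses.asdict(cfg), "seed": cfg.seed,
                "input_checksums": checksums}, outdir / "run_manifest.json")
    return outdir
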