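"""End-to-end orchestration and report rendering.

``run_pipeline`` executes the panel-development stages in workflow order —
simulate -> filter -> trim -> screen -> select -> qc — writing each
stage's artifacts and a manifest (parameter values, input hashes, package
version) into a run directory, so a run is reproducible bit-for-bit from
its config.  ``render_reports`` turns the artifacts into the four
human-readable summaries: per-collection samples/missingness, the
per-round optimization table, the subset-selection ranking, and the panel
composition (microhaplotype vs single-SNP loci).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .filters import apply_filters
from .io import write_fasta, write_genotypes, write_panel_tables
from .primers import prepare_panel
from .qc import run_optimization
from .selection import (
    DEFAULT_SCHEMES,
    SubsetScheme,
    build_subsets,
    compare_subsets,
    dapc,
    diversity_stats,
    pairwise_fst,
    per_locus_temporal_fst,
)
from .simulate import (
    DriftParams,
    ReadSimParams,
    naive_primer_candidates,
    simulate_temporal_genotypes,
)

__all__ = ["RunConfig", "run_pipeline", "render_reports", "STAGES"]

STAGES = ("simulate", "filter", "trim", "screen", "select", "qc")


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run.

    One master ``seed``; every randomized stage consumes a stage-derived
    seed recorded in its manifest.  Scheme sizes scale with
    ``subset_total`` so reduced-size synthetic runs keep the five-scheme
    structure.
    """

    out_dir: str = "gtpanel_run"
    seed: int = 0
    # simulate: raw candidate loci; SNP-position trimming and primer
    # screening thin the pool before the 500-locus subsets are drawn
    n_loci: int = 1500
    samples_per_year: int = 30
    locus_len: int = 150
    genome_len: int = 400_000
    missingness: float = 0.03
    # filter
    min_mean_depth: float = 20.0
    max_ind_missing: float = 0.25
    alpha: float = 0.05
    correction: str = "bonferroni"
    # select
    subset_total: int = 500
    n_perm: int = 1000
    n_boot: int = 200
    n_pc: int | str = 30
    alignment: str = "procrustes"
    compute_diversity: bool = True
    compute_pairwise_fst: bool = False
    # qc
    panel_size: int | None = None  # None: use the winning scheme's loci
    interaction_fraction: float = 0.6
    hot_fraction: float = 0.25
    hot_weight: float = 12.0
    depth_mean: float = 50.0
    error_rate: float = 0.001
    max_rounds: int = 6
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + STAGES.index(stage) + 1) % (2**31)

    def schemes(self):
        t = self.subset_total
        return (
            SubsetScheme("Fst500", t, 0),
            SubsetScheme("Rdm500", 0, t),
            SubsetScheme("Fst350+Rdm150", int(0.7 * t), t - int(0.7 * t)),
            SubsetScheme("Fst250+Rdm250", t // 2, t - t // 2),
            SubsetScheme("Fst150+Rdm350", int(0.3 * t), t - int(0.3 * t)),
        )


def _sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(run_dir, stage, params, inputs, outputs):
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "inputs": {os.path.basename(p): _sha(p) for p in inputs},
        "outputs": {os.path.basename(p): _sha(p) for p in outputs},
    }
    path = os.path.join(run_dir, f"manifest_{stage}.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def run_pipeline(config: RunConfig, stages=STAGES) -> str:
    """Execute the requested stages in workflow order; returns the run dir.

    Later stages consume the artifacts of earlier ones from the run
    directory, so a prefix of the stage list must already have run (a
    missing dependency raises before any work).
    """
    stages = [s for s in STAGES if s in set(stages)]
    if not stages:
        raise ValueError("no known stage requested")
    run_dir = config.out_dir
    os.makedirs(run_dir, exist_ok=True)

    def need(fname, stage):
        path = os.path.join(run_dir, fname)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"stage {stage!r} requires {fname} from an earlier stage"
            )
        return path

    state: dict = {}
    for stage in stages:
        handler = _STAGE_HANDLERS[stage]
        handler(config, run_dir, state, need)
    return run_dir


def _stage_simulate(cfg: RunConfig, run_dir, state, need):
    seed = cfg.stage_seed("simulate")
    dp = DriftParams(
        n_loci=cfg.n_loci,
        samples_per_year=cfg.samples_per_year,
        missingness=cfg.missingness,
        seed=seed + 1,
    )
    gm, truth = simulate_temporal_genotypes(dp)
    # embed loci whose SNP structure matches the simulated catalogues
    from .simulate import embed_loci_for_catalogues

    genome, loci = embed_loci_for_catalogues(
        gm.loci,
        gm.alleles,
        locus_len=cfg.locus_len,
        genome_len=cfg.genome_len,
        seed=seed,
    )

    geno_path = os.path.join(run_dir, "genotypes.tsv")
    write_genotypes(gm, geno_path)
    ref_path = os.path.join(run_dir, "reference.fa")
    write_fasta(genome, ref_path)
    loci_path = os.path.join(run_dir, "loci.tsv")
    with open(loci_path, "w") as fh:
        fh.write("# simulated locus metadata\n")
        fh.write("locus\tcontig\tstart\tlength\tmean_depth\tsnp_offsets\tsnp_alleles\n")
        for l in loci:
            fh.write(
                "\t".join(
                    [
                        l.locus_id,
                        l.contig,
                        str(l.start),
                        str(len(l.sequence)),
                        f"{l.mean_depth:.3f}",
                        ",".join(str(s.offset) for s in l.snps),
                        ";".join("/".join(s.alleles) for s in l.snps),
                    ]
                )
                + "\n"
            )
    truth_path = os.path.join(run_dir, "truth_frequencies.tsv")
    with open(truth_path, "w") as fh:
        fh.write("# true allele frequencies per sampling year\n")
        fh.write("year\tlocus\tallele\tfrequency\n")
        for year in truth.years:
            for j, lid in enumerate(truth.loci):
                for a, freq in zip(truth.alleles[j], truth.freq(year, j)):
                    fh.write(f"{year}\t{lid}\t{a}\t{freq:.6f}\n")
    state["gm"], state["loci"], state["genome"] = gm, loci, genome
    _write_manifest(
        run_dir,
        "simulate",
        {"seed": seed, **{k: getattr(cfg, k) for k in ("n_loci", "samples_per_year", "locus_len", "genome_len", "missingness")}},
        [],
        [geno_path, ref_path, loci_path, truth_path],
    )


def _load_state(cfg, run_dir, state, need, what):
    """Reload artifacts for stages starting mid-pipeline."""
    from .io import load_genotypes, load_reference
    from .model import MicrohapLocus, SnpSite

    if "gm" in state:
        return
    geno = need("genotypes.tsv", what)
    ref = need("reference.fa", what)
    loci_path = need("loci.tsv", what)
    state["gm"] = load_genotypes(geno)
    state["genome"] = load_reference(ref)
    loci = []
    with open(loci_path) as fh:
        rows = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip() and not ln.startswith("#")]
    for row in rows[1:]:
        lid, contig, start, _length, depth, offs, alls = row
        snps = tuple(
            SnpSite(lid, int(o), tuple(a.split("/")))
            for o, a in zip(offs.split(","), alls.split(";"))
            if o
        )
        contig_seq = state["genome"][contig]
        seq = contig_seq[int(start) : int(start) + int(_length)]
        loci.append(
            MicrohapLocus(lid, seq, snps, contig=contig, start=int(start), mean_depth=float(depth))
        )
    state["loci"] = loci


def _stage_filter(cfg: RunConfig, run_dir, state, need):
    _load_state(cfg, run_dir, state, need, "filter")
    seed = cfg.stage_seed("filter")
    report, gm_f, loci_f = apply_filters(
        state["loci"],
        state["gm"],
        min_mean_depth=cfg.min_mean_depth,
        max_ind_missing=cfg.max_ind_missing,
        alpha=cfg.alpha,
        correction=cfg.correction,
        seed=seed,
    )
    out_geno = os.path.join(run_dir, "genotypes.filtered.tsv")
    write_genotypes(gm_f, out_geno)
    rep_path = os.path.join(run_dir, "filter_report.tsv")
    with open(rep_path, "w") as fh:
        fh.write("# locus filter outcomes\n")
        fh.write("locus\tstatus\treason\n")
        for l in report.retained_loci:
            fh.write(f"{l}\tretained\t.\n")
        for l, r in sorted(report.excluded_loci.items()):
            fh.write(f"{l}\texcluded\t{r}\n")
    summary_path = os.path.join(run_dir, "filter_summary.json")
    with open(summary_path, "w") as fh:
        json.dump(report.counts(), fh, indent=1, sort_keys=True)
    state["gm_filtered"], state["loci_filtered"] = gm_f, loci_f
    _write_manifest(
        run_dir,
        "filter",
        {"seed": seed, "min_mean_depth": cfg.min_mean_depth, "max_ind_missing": cfg.max_ind_missing, "alpha": cfg.alpha, "correction": cfg.correction},
        [os.path.join(run_dir, "genotypes.tsv")],
        [out_geno, rep_path, summary_path],
    )


def _stage_trim(cfg: RunConfig, run_dir, state, need):
    from .primers import Removed, build_probes, filter_template_length, trim_snps_for_primers

    if "loci_filtered" not in state:
        _load_state(cfg, run_dir, state, need, "trim")
        state.setdefault("loci_filtered", state["loci"])
        state.setdefault("gm_filtered", state["gm"])
    trimmed, removed = [], {}
    for locus in state["loci_filtered"]:
        t = trim_snps_for_primers(locus)
        if isinstance(t, Removed):
            removed[locus.locus_id] = t.reason
            continue
        t = filter_template_length(t)
        if isinstance(t, Removed):
            removed[locus.locus_id] = t.reason
            continue
        trimmed.append((locus, t, build_probes(t)))
    state["trimmed"] = trimmed
    path = os.path.join(run_dir, "trimmed_loci.tsv")
    with open(path, "w") as fh:
        fh.write("# SNP-position trimming outcomes\n")
        fh.write("locus\tstatus\tkept_start\tkept_end\tn_snps\tdiscarded_snps\n")
        for locus, t, _p in trimmed:
            fh.write(
                f"{locus.locus_id}\tkept\t{t.kept_start}\t{t.kept_end}\t{len(t.snps)}\t{t.discarded_snps}\n"
            )
        for lid, reason in sorted(removed.items()):
            fh.write(f"{lid}\t{reason}\t.\t.\t.\t.\n")
    _write_manifest(run_dir, "trim", {"flank": 33, "max_template_len": 150}, [], [path])


def _stage_screen(cfg: RunConfig, run_dir, state, need):
    if "trimmed" not in state:
        raise FileNotFoundError("stage 'screen' requires the trim stage in the same run")
    loci = [locus for locus, _t, _p in state["trimmed"]]
    candidates = {
        locus.locus_id: naive_primer_candidates for locus in loci
    }
    # prepare_panel re-runs trimming internally; reuse its chain end-to-end
    panel, removals = prepare_panel(loci, state["genome"], candidates)
    state["panel"] = panel
    out = write_panel_tables(panel, run_dir)
    _write_manifest(
        run_dir,
        "screen",
        {"n_panel": len(panel), "removals": removals},
        [],
        list(out.values()),
    )


def _stage_select(cfg: RunConfig, run_dir, state, need):
    if "panel" not in state or "gm_filtered" not in state:
        raise FileNotFoundError("stage 'select' requires simulate..screen in the same run")
    seed = cfg.stage_seed("select")
    gm = state["gm_filtered"]
    with_primers = [e.locus_id for e in state["panel"]]
    gm_pool = gm.subset_loci([l for l in gm.loci if l in set(with_primers)])
    fst = per_locus_temporal_fst(gm_pool)
    theta_path = os.path.join(run_dir, "per_locus_fst.tsv")
    with open(theta_path, "w") as fh:
        fh.write("# per-locus temporal Weir-Cockerham theta\n")
        fh.write("locus\ttheta\n")
        for f in fst:
            fh.write(f"{f.locus_id}\t{f.theta:.6f}\n")

    schemes = cfg.schemes()
    subsets = build_subsets(fst, schemes, seed=seed)
    complete = dapc(gm_pool, n_pc=cfg.n_pc, seed=seed)
    sub_results = {
        name: dapc(gm_pool.subset_loci(ids), n_pc=cfg.n_pc, seed=seed)
        for name, ids in subsets.items()
    }
    report = compare_subsets(complete, sub_results, alignment=cfg.alignment)
    if cfg.compute_diversity:
        report.diversity["complete"] = diversity_stats(
            gm_pool, n_boot=cfg.n_boot, seed=seed
        )
    if cfg.compute_pairwise_fst:
        report.pairwise["complete"] = pairwise_fst(
            gm_pool, n_perm=cfg.n_perm, n_boot=cfg.n_boot, seed=seed
        )
    state["selection"] = report
    state["subsets"] = subsets
    rank_path = os.path.join(run_dir, "selection_ranking.tsv")
    report.summary.to_csv(rank_path, sep="\t", index_label="scheme")
    dist_path = os.path.join(run_dir, "selection_distances.tsv")
    report.distances.to_csv(dist_path, sep="\t", index_label="scheme")
    chosen_path = os.path.join(run_dir, "chosen_subset.txt")
    with open(chosen_path, "w") as fh:
        fh.write(report.chosen + "\n")
        for lid in subsets[report.chosen]:
            fh.write(lid + "\n")
    _write_manifest(
        run_dir,
        "select",
        {"seed": seed, "subset_total": cfg.subset_total, "alignment": cfg.alignment, "n_pc": cfg.n_pc},
        [theta_path],
        [rank_path, dist_path, chosen_path],
    )


def _stage_qc(cfg: RunConfig, run_dir, state, need):
    if "panel" not in state:
        raise FileNotFoundError("stage 'qc' requires simulate..select in the same run")
    seed = cfg.stage_seed("qc")
    rng = np.random.default_rng(seed)
    gm = state["gm_filtered"]
    chosen_ids = set(state["subsets"][state["selection"].chosen])
    panel = [e for e in state["panel"] if e.locus_id in chosen_ids]
    # keep only loci whose panel SNP set equals the discovery SNP set, so
    # the truth genotypes decompose one-to-one for concordance
    gm_idx = {l: j for j, l in enumerate(gm.loci)}
    panel = [
        e
        for e in panel
        if len(e.locus.snps) == len(gm.alleles[gm_idx[e.locus_id]][0])
    ]
    if cfg.panel_size:
        panel = panel[: cfg.panel_size]
    gm_panel = gm.subset_loci([l for l in gm.loci if any(e.locus_id == l for e in panel)])
    fst_by = {
        f.locus_id: f.theta for f in per_locus_temporal_fst(gm_panel)
    }
    ids = [e.locus_id for e in panel]
    n_hot = max(2, int(cfg.hot_fraction * len(ids)))
    hot = list(rng.choice(ids, size=n_hot, replace=False))
    weights = {lid: (cfg.hot_weight if lid in set(hot) else 1.0) for lid in ids}
    # QC rounds use one collection's worth of individuals
    first_year = gm_panel.collection_labels()[0]
    inds = [i for i, c in zip(gm_panel.individuals, gm_panel.collections) if c == first_year]
    gm_round = gm_panel.subset_individuals(inds)
    rp = ReadSimParams(
        depth_mean=cfg.depth_mean,
        error_rate=cfg.error_rate,
        interaction_fraction=cfg.interaction_fraction,
        interaction_weights=weights,
        seed=seed,
    )
    assessments, panel_out = run_optimization(
        list(panel), gm_round, rp, per_locus_fst=fst_by, max_rounds=cfg.max_rounds, seed=seed
    )
    rounds_path = os.path.join(run_dir, "optimization_rounds.tsv")
    with open(rounds_path, "w") as fh:
        fh.write("# multiplex optimization rounds\n")
        fh.write("round\tinteractions_pct\taccuracy_pct\tstop\treason\tactive_loci\n")
        for k, a in enumerate(assessments, 1):
            acc = "NA" if a.accuracy is None else f"{100 * a.accuracy:.1f}"
            fh.write(
                f"{k}\t{100 * a.proportion_interactions:.1f}\t{acc}\t{a.stop}\t{a.reason}\t{a.active_loci}\n"
            )
    state["assessments"], state["panel_final"] = assessments, panel_out
    _write_manifest(
        run_dir,
        "qc",
        {"seed": seed, "interaction_fraction": cfg.interaction_fraction, "hot": sorted(hot)},
        [],
        [rounds_path],
    )


_STAGE_HANDLERS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "trim": _stage_trim,
    "screen": _stage_screen,
    "select": _stage_select,
    "qc": _stage_qc,
}


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def render_reports(run_dir) -> str:
    """Render the human-readable summary of a run directory."""
    if not os.path.isdir(run_dir) or not os.listdir(run_dir):
        raise FileNotFoundError(f"empty or missing run directory: {run_dir}")
    sections = []

    geno = os.path.join(run_dir, "genotypes.tsv")
    if os.path.exists(geno):
        from .io import load_genotypes

        gm = load_genotypes(geno)
        miss = gm.individual_missingness()
        rows = []
        for lab in gm.collection_labels():
            idx = [i for i, c in enumerate(gm.collections) if c == lab]
            rows.append(
                {"collection": lab, "n": len(idx), "missing": float(np.mean(miss[idx]))}
            )
        t = pd.DataFrame(rows).to_string(index=False, float_format=lambda x: f"{x:.3f}")
        sections.append("== Collections ==\n" + t)

    rounds = os.path.join(run_dir, "optimization_rounds.tsv")
    if os.path.exists(rounds):
        t = pd.read_csv(rounds, sep="\t", comment="#")
        sections.append("== Optimization rounds ==\n" + t.to_string(index=False))

    ranking = os.path.join(run_dir, "selection_ranking.tsv")
    if os.path.exists(ranking):
        t = pd.read_csv(ranking, sep="\t")
        sections.append("== Subset ranking (mean distance to complete DAPC) ==\n" + t.to_string(index=False))

    probe_table = os.path.join(run_dir, "probe_table.tsv")
    if os.path.exists(probe_table):
        t = pd.read_csv(probe_table, sep="\t", comment="#")
        per_locus = t.groupby("locus").size()
        n_multi = int((per_locus > 1).sum())
        n_single = int((per_locus == 1).sum())
        sections.append(
            "== Panel composition ==\n"
            f"loci: {len(per_locus)}  SNPs: {len(t)}\n"
            f"microhaplotype loci (2+ SNPs): {n_multi}  single-SNP loci: {n_single}"
        )
    if not sections:
        raise FileNotFoundError(f"no stage reports found in {run_dir}")
    return "\n\n".join(sections)
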