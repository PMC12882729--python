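"""Readers and writers for the external formats the toolkit touches.

Formats
-------
* reference genomes / locus templates: FASTA (via Biopython).
* SNP input: VCF (via cyvcf2); each biallelic record becomes a single-SNP
  locus.  Microhaplotype input requires the phased tab-delimited table.
* genotype tables: tab-delimited, one row per individual, calls serialized
  as "ACT/ATT" ("." for missing).
* panel tables: a primer table and an eight-column probe table in the style
  consumed by GTscore-like amplicon read counters, plus a template FASTA.

All writers emit a header line beginning with ``#``.  Internal coordinates
are 0-based half-open; VCF positions are converted on input.
"""

from __future__ import annotations

import os
from collections import OrderedDict

from Bio import SeqIO

from .model import (
    MISSING,
    GenotypeMatrix,
    MicrohapLocus,
    PanelEntry,
    PrimerPair,
    ProbeRecord,
    SnpSite,
)

__all__ = [
    "load_reference",
    "load_genotypes",
    "write_genotypes",
    "write_panel_tables",
    "read_panel_tables",
    "PROBE_TABLE_COLUMNS",
]

#: Fixed probe-table dialect (one row per SNP).  The layout mirrors the
#: eight-column tables used by GTscore-style read counters; a strict reader
#: rejects anything else.
PROBE_TABLE_COLUMNS = (
    "locus",
    "ploidy",
    "alleles",
    "probes",
    "fwd_primer",
    "snp_offset",
    "allele_correction",
    "notes",
)


class ParseError(ValueError):
    """Raised when an input file does not conform to its dialect."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_reference(path) -> "OrderedDict[str, str]":
    """Load a FASTA file as an ordered name -> uppercase-sequence mapping.

    Duplicate record names raise :class:`ParseError`.
    """
    seqs: OrderedDict[str, str] = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA record name: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def _parse_call(token: str, line_no: int, locus: str):
    token = token.strip()
    if token in (".", "./.", "", "NA"):
        return None
    parts = token.upper().split("/")
    if len(parts) != 2 or not all(p and set(p) <= set("ACGT") for p in parts):
        raise ParseError(f"line {line_no}: unknown allele code {token!r} at {locus}")
    return tuple(parts)


def load_genotypes(path, collection_map: dict | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from a tab-delimited table or a VCF.

    Table dialect: optional leading ``#`` comment lines, then a header row
    ``individual<TAB>collection<TAB><locus1>...`` (the ``collection`` column
    may be omitted when ``collection_map`` supplies the labels) and one row
    per individual with calls like ``ACT/ATT`` or ``.`` for missing.

    VCF input (detected by extension ``.vcf``/``.vcf.gz``) yields one
    single-SNP locus per biallelic-or-multiallelic SNP record, with 1-based
    positions converted to 0-based internal locus ids ``contig:pos0``; a
    ``collection_map`` is then required.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _load_genotypes_vcf(path, collection_map)
    return _load_genotypes_table(path, collection_map)


def _load_genotypes_table(path, collection_map) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [
            (i + 1, ln.rstrip("\n"))
            for i, ln in enumerate(fh)
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise ParseError(f"{path}: empty genotype table (no header)")
    header = lines[0][1].split("\t")
    if header[0] != "individual":
        raise ParseError(f"{path}: first header column must be 'individual'")
    has_coll = len(header) > 1 and header[1] == "collection"
    loci = header[2:] if has_coll else header[1:]

    individuals, collections, raw_calls = [], [], []
    for line_no, ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"line {line_no}: expected {len(header)} fields")
        ind = fields[0]
        if has_coll:
            coll = fields[1]
            tokens = fields[2:]
        else:
            if collection_map is None or ind not in collection_map:
                raise ParseError(f"line {line_no}: individual {ind} has no collection label")
            coll = collection_map[ind]
            tokens = fields[1:]
        individuals.append(ind)
        collections.append(coll)
        raw_calls.append(
            [_parse_call(t, line_no, loci[j]) for j, t in enumerate(tokens)]
        )

    # build per-locus allele catalogues (sorted for determinism)
    alleles = []
    for j in range(len(loci)):
        seen = set()
        for row in raw_calls:
            if row[j] is not None:
                seen.update(row[j])
        alleles.append(sorted(seen))

    import numpy as np

    calls = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int16)
    for i, row in enumerate(raw_calls):
        for j, call in enumerate(row):
            if call is not None:
                cat = alleles[j]
                calls[i, j] = sorted(cat.index(a) for a in call)
    return GenotypeMatrix(individuals, collections, loci, alleles, calls)


def _load_genotypes_vcf(path, collection_map) -> GenotypeMatrix:
    import numpy as np
    from cyvcf2 import VCF

    if collection_map is None:
        raise ParseError("VCF input requires a collection_map (id -> year)")
    vcf = VCF(path)
    individuals = list(vcf.samples)
    missing_label = [s for s in individuals if s not in collection_map]
    if missing_label:
        raise ParseError(f"individuals without collection label: {missing_label}")
    collections = [collection_map[s] for s in individuals]

    loci, alleles, columns = [], [], []
    for var in vcf:
        var_alleles = [var.REF] + list(var.ALT)
        if any(len(a) != 1 or a.upper() not in "ACGT" for a in var_alleles):
            raise ParseError(
                f"{var.CHROM}:{var.POS}: unknown allele code {var_alleles} "
                "(only SNPs supported)"
            )
        loci.append(f"{var.CHROM}:{var.start}")  # 0-based internal
        alleles.append([a.upper() for a in var_alleles])
        col = np.full((len(individuals), 2), MISSING, dtype=np.int16)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                col[i] = sorted((a, b))
        columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(individuals), 0, 2), dtype=np.int16)
    )
    return GenotypeMatrix(individuals, collections, loci, alleles, calls)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the tab-delimited genotype table (round-trips via the loader)."""
    with open(path, "w") as fh:
        fh.write("# gtpanel genotype table; calls are haplotype1/haplotype2, '.' = missing\n")
        fh.write("individual\tcollection\t" + "\t".join(gm.loci) + "\n")
        for i, ind in enumerate(gm.individuals):
            row = [ind, str(gm.collections[i])]
            row += [gm.call_string(i, j) for j in range(gm.n_loci)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# panel tables
# ---------------------------------------------------------------------------

def write_panel_tables(panel: list[PanelEntry], out_dir) -> dict:
    """Write primer table, probe table and template FASTA for a panel.

    Returns the paths written.  Raises :class:`ParseError` if any entry
    lacks a primer pair.
    """
    if not panel:
        raise ParseError("empty panel")
    missing = [e.locus_id for e in panel if e.primers is None]
    if missing:
        raise ParseError(f"panel entries lacking primers: {missing}")
    os.makedirs(out_dir, exist_ok=True)
    primer_path = os.path.join(out_dir, "primer_table.tsv")
    probe_path = os.path.join(out_dir, "probe_table.tsv")
    template_path = os.path.join(out_dir, "templates.fa")

    with open(primer_path, "w") as fh:
        fh.write("# gtpanel primer table\n")
        fh.write(
            "locus\tfwd\trev\trank\tproduct_start\tproduct_end\tactive\tremoved_reason\n"
        )
        for e in panel:
            p = e.primers
            fh.write(
                "\t".join(
                    [
                        e.locus_id,
                        p.fwd_seq,
                        p.rev_seq,
                        str(p.rank),
                        str(p.product_start),
                        "." if p.product_end is None else str(p.product_end),
                        "1" if e.active else "0",
                        e.removed_reason or ".",
                    ]
                )
                + "\n"
            )

    with open(probe_path, "w") as fh:
        fh.write("# gtpanel probe table (one row per SNP)\n")
        fh.write("\t".join(PROBE_TABLE_COLUMNS) + "\n")
        for e in panel:
            for pr in e.probes:
                fh.write(
                    "\t".join(
                        [
                            e.locus_id,
                            "2",
                            ",".join(pr.alleles),
                            ",".join(pr.probes),
                            e.primers.fwd_seq,
                            str(pr.snp_offset),
                            ",".join("1" for _ in pr.alleles),
                            "truncated" if pr.truncated else ".",
                        ]
                    )
                    + "\n"
                )

    templates = {}
    for e in panel:
        desc = []
        if e.locus.contig is not None:
            desc.append(f"contig={e.locus.contig}")
        if e.locus.start is not None:
            desc.append(f"start={e.locus.start}")
        if e.locus.mean_depth is not None:
            desc.append(f"mean_depth={e.locus.mean_depth:.17g}")
        name = e.locus_id + (" " + " ".join(desc) if desc else "")
        templates[name] = e.locus.sequence
    write_fasta(templates, template_path)
    return {"primers": primer_path, "probes": probe_path, "templates": template_path}


def _read_table(path, expect_columns=None, strict=True):
    with open(path) as fh:
        rows = [
            ln.rstrip("\n").split("\t")
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if not rows:
        raise ParseError(f"{path}: empty table")
    header, body = rows[0], rows[1:]
    if expect_columns is not None and strict and tuple(header) != tuple(expect_columns):
        raise ParseError(
            f"{path}: unknown table layout {header}; expected {list(expect_columns)}"
        )
    return header, body


def read_panel_tables(in_dir, strict: bool = True) -> list[PanelEntry]:
    """Read a panel written by :func:`write_panel_tables`."""
    primer_path = os.path.join(in_dir, "primer_table.tsv")
    probe_path = os.path.join(in_dir, "probe_table.tsv")
    template_path = os.path.join(in_dir, "templates.fa")

    templates: dict[str, dict] = {}
    for rec in SeqIO.parse(template_path, "fasta"):
        meta = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
        templates[rec.id] = {"seq": str(rec.seq).upper(), **meta}

    _, primer_rows = _read_table(primer_path, strict=False)
    _, probe_rows = _read_table(probe_path, PROBE_TABLE_COLUMNS, strict=strict)

    probes_by_locus: dict[str, list[ProbeRecord]] = {}
    snps_by_locus: dict[str, list[SnpSite]] = {}
    for row in probe_rows:
        if len(row) != len(PROBE_TABLE_COLUMNS):
            raise ParseError(f"{probe_path}: probe row with {len(row)} columns")
        locus, _pl, alleles, probes, _fwd, off, _corr, notes = row
        alleles_t = tuple(alleles.split(","))
        probes_t = tuple(probes.split(","))
        pr = ProbeRecord(locus, int(off), alleles_t, probes_t, truncated=notes == "truncated")
        probes_by_locus.setdefault(locus, []).append(pr)
        snps_by_locus.setdefault(locus, []).append(SnpSite(locus, int(off), alleles_t))

    panel = []
    for row in primer_rows:
        locus, fwd, rev, rank, pstart, pend, active, reason = row
        info = templates[locus]
        mh = MicrohapLocus(
            locus,
            info["seq"],
            tuple(sorted(snps_by_locus.get(locus, []), key=lambda s: s.offset)),
            contig=info.get("contig"),
            start=int(info["start"]) if "start" in info else None,
            mean_depth=float(info["mean_depth"]) if "mean_depth" in info else None,
        )
        pair = PrimerPair(
            locus,
            fwd,
            rev,
            rank=int(rank),
            product_start=int(pstart),
            product_end=None if pend == "." else int(pend),
        )
        panel.append(
            PanelEntry(
                mh,
                pair,
                tuple(sorted(probes_by_locus.get(locus, []), key=lambda p: p.snp_offset)),
                active=active == "1",
                removed_reason=None if reason == "." else reason,
            )
        )
    return panel
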