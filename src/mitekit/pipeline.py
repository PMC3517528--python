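"""End-to-end orchestration: mine, annotate, stack, summarize.

``run_pipeline`` executes the full analysis shape on any genome +
reference element: copy mining, structural annotation (TIR/TSD/ORF,
optional gene context), reference-anchored alignment and majority
consensus, within/between-species divergence, a bootstrap-supported
NJ tree, the TSD position-frequency profile with hAT family call, and
optional in-silico PCR. All outputs are plain text (GFF3, TSV, FASTA,
Newick, JSON) and byte-deterministic for a fixed config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotate as _annotate
from . import consensus as _consensus
from . import divergence as _divergence
from . import phylogeny as _phylogeny
from . import pcr as _pcr
from . import tsd as _tsd
from .mining import MiningParams, mine_copies
from .seqio import (
    parse_species, read_fasta, read_gff3_intervals, write_annotations, write_fasta,
    SequenceRecord,
)

log = logging.getLogger("mitekit")

DEFAULTS = dict(
    seed=0,
    tir_budget=1,
    tsd_budget=1,
    tsd_len=8,
    min_tir=5,
    max_tir=30,
    near_bp=2000,
    metric="t92_gamma",
    gamma_a=2.0,
    n_bootstrap=100,
    min_coverage=0.5,
    orf_min_aa=100,
    pcr_budget=2,
    pcr_max_len=5000,
)


class ConfigurationError(ValueError):
    pass


def _copies_table(copies) -> pd.DataFrame:
    rows = []
    for c in copies:
        rows.append(
            dict(
                copy_id=c.copy_id,
                seq_id=c.interval.seq_id,
                start=c.interval.start,
                end=c.interval.end,
                strand=c.interval.strand,
                length=len(c.copy_seq),
                identity=round(c.identity, 4),
                **{k: v for k, v in c.annotations.items() if k != "class_rationale"},
            )
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict) -> Path:
    """Run every stage and write a report directory; returns its path.

    Required config keys: ``genome`` (FASTA path or list of paths),
    ``element`` (reference FASTA) and ``out`` (directory). Optional:
    ``genes`` (GFF3), ``primers`` (2-column TSV), ``seed``, mining
    parameters under ``mining``, and the stage parameters in
    :data:`DEFAULTS`.
    """
    cfg = {**DEFAULTS, **config}
    for key in ("genome", "element", "out"):
        if key not in cfg:
            raise ConfigurationError(f"missing required config key {key!r}")
    genome_paths = cfg["genome"]
    if isinstance(genome_paths, (str, Path)):
        genome_paths = [genome_paths]
    for p in list(genome_paths) + [cfg["element"]] + (
        [cfg["genes"]] if cfg.get("genes") else []
    ) + ([cfg["primers"]] if cfg.get("primers") else []):
        if not Path(p).exists():
            raise ConfigurationError(f"input file not found: {p}")

    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%s out=%s", cfg["seed"], out)

    genomes: list[SequenceRecord] = []
    for p in genome_paths:
        genomes.extend(read_fasta(p))
    reference = read_fasta(cfg["element"])[0]
    mparams = MiningParams(**cfg.get("mining", {}))

    # --- mine + annotate -------------------------------------------------
    copies = mine_copies(genomes, reference, mparams)
    if not copies:
        log.warning("no copies of %s found in the input genomes", reference.id)
    _annotate.annotate_copies(
        copies, len(reference.residues),
        min_tir=cfg["min_tir"], max_tir=cfg["max_tir"], tir_budget=cfg["tir_budget"],
        tsd_len=cfg["tsd_len"], tsd_budget=cfg["tsd_budget"],
        orf_min_aa=cfg["orf_min_aa"],
    )
    if cfg.get("genes"):
        genes = read_gff3_intervals(cfg["genes"], feature_types=["gene"])
        labels = _annotate.gene_context(
            copies, genes, cfg["near_bp"], known_seq_ids={g.id for g in genomes}
        )
        for c, lab in zip(copies, labels):
            c.annotations["gene_context"] = lab

    seq_lengths = {g.id: len(g.residues) for g in genomes}
    write_annotations(copies, out / "copies.gff3", seq_lengths)
    table = _copies_table(copies)
    table.to_csv(out / "copies.tsv", sep="\t", index=False)

    summary: dict = {
        "seed": cfg["seed"],
        "reference_id": reference.id,
        "reference_len": len(reference.residues),
        "n_copies": len(copies),
    }

    if len(copies) >= 1:
        n = len(copies)
        tir_ok = sum(bool(c.annotations["tir_present"]) for c in copies)
        tsd_ok = sum(bool(c.annotations["tsd_present"]) for c in copies)
        classes = pd.Series([c.annotations["copy_class"] for c in copies])
        summary.update(
            pct_tir_conserved=round(100.0 * tir_ok / n, 1),
            pct_tsd_conserved=round(100.0 * tsd_ok / n, 1),
            class_counts=classes.value_counts().sort_index().to_dict(),
        )

    # --- alignment, consensus, divergence, tree --------------------------
    if len(copies) >= 2:
        # species labels come from the genome sequence headers
        for c in copies:
            sp = parse_species(c.interval.seq_id) or c.interval.seq_id
            c.copy_id = f"{sp}|{c.copy_id}"
        aln_all = _consensus.stack_on_reference(copies, reference)
        _consensus.write_alignment(aln_all, out / "alignment.fasta")
        prof = _consensus.majority_consensus(aln_all, cfg["min_coverage"])
        write_fasta(
            [SequenceRecord(f"{reference.id}_consensus", prof.consensus)],
            out / "consensus.fasta",
        )
        pd.DataFrame(
            prof.counts, columns=list("ACGT-")
        ).to_csv(out / "profile.tsv", sep="\t", index_label="column")

        # copy-only alignment (reference row excluded from statistics)
        aln = _consensus.StackedAlignment(
            aln_all.row_ids[1:], aln_all.species[1:], aln_all.matrix[1:]
        )
        div = _divergence.group_divergence(aln)
        div.to_csv(out / "divergence.tsv", sep="\t")
        summary["overall_mean_divergence_pct"] = round(
            _divergence.overall_mean_divergence(aln), 2
        )
        if aln.n_rows >= 4:
            tree = _phylogeny.bootstrap_support(
                aln, metric=cfg["metric"], gamma_a=cfg["gamma_a"],
                n_reps=cfg["n_bootstrap"], seed=cfg["seed"],
            )
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")

        tsds = [
            c.annotations["tsd_seq"]
            for c in copies
            if c.annotations["tsd_present"] and c.annotations["tsd_seq"]
        ]
        if tsds:
            pfm = _tsd.build_pfm(tsds)
            pfm.to_frame().to_csv(out / "tsd_pfm.tsv", sep="\t")
            cons = _tsd.call_consensus(pfm)
            summary["tsd_consensus"] = cons
            summary["tsd_family"] = _tsd.classify_family(cons)
            (out / "tsd_logo.txt").write_text(_tsd.text_logo(pfm) + "\n")

    # --- optional in-silico PCR ------------------------------------------
    if cfg.get("primers"):
        primers = _pcr.read_primer_tsv(cfg["primers"])
        ids = sorted(primers)
        rows = []
        for i, fid in enumerate(ids):
            for rid in ids[i + 1 :]:
                for g in genomes + [reference]:
                    for iv, length in _pcr.predict_amplicons(
                        g, primers[fid], primers[rid],
                        cfg["pcr_budget"], cfg["pcr_max_len"],
                    ):
                        rows.append(
                            dict(fwd=fid, rev=rid, seq_id=iv.seq_id,
                                 start=iv.start, end=iv.end, length=length)
                        )
        pd.DataFrame(rows).to_csv(out / "amplicons.tsv", sep="\t", index=False)
        summary["n_amplicons"] = len(rows)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log.info("pipeline done: %d copies", len(copies))
    return out
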