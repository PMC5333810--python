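"""Stage orchestration behind the command-line interface.

Every function is a pure function of (inputs, parameters, seed): re-running
with the same arguments produces byte-identical outputs.  All randomness
flows from one top-level seed; the bootstrap stage derives its stream as
``seed + 1000`` so stage subsets remain reproducible.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Optional

from . import blocks, classifier as _classify, domains, seqio, synthetic, trees

log = logging.getLogger("lophopax")

BOOTSTRAP_SEED_OFFSET = 1000


def _outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_classify(fasta_path, out_dir, max_junction: int = 20) -> Path:
    """Annotate + classify a FASTA; write reclassification and annotation TSVs."""
    out = _outdir(out_dir)
    records = seqio.read_fasta(fasta_path)
    profiles = domains.default_profiles()
    registry = domains.load_motif_registry()
    calls, ann_rows = [], []
    for rec in records:
        ann = domains.annotate(rec, profiles, registry, max_junction=max_junction)
        call = _classify.classify(ann)
        calls.append(call)
        for h in ann.hits:
            ann_rows.append((rec.id, h.kind, h.start, h.end, f"{h.score:.4f}",
                             h.complete, h.label))
    report = _classify.batch_report(calls)
    report_path = out / "reclassification.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    with open(out / "annotation.tsv", "w") as fh:
        fh.write("record\tkind\tstart\tend\tscore\tcomplete\tlabel\n")
        for row in ann_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    counts = Counter(c.proposed_name if c.status == "ok" else "no-PRD" for c in calls)
    if not records:
        log.warning("empty input FASTA: header-only report written")
    log.info("classified %d records: %s", len(records), dict(sorted(counts.items())))
    return report_path


def run_tree(aligned_path, out_dir,
             block_params: Optional[blocks.BlockFilterParams] = None,
             phylo_params: Optional[trees.PhyloParams] = None,
             calls_tsv=None) -> Path:
    """Curate an alignment, build the bootstrap NJ tree, report monophyly."""
    out = _outdir(out_dir)
    block_params = block_params or blocks.BlockFilterParams()
    phylo_params = phylo_params or trees.PhyloParams()
    log.info("tree stage config: %s / %s", block_params, phylo_params)
    aln = seqio.read_alignment(aligned_path)
    curated, mask = blocks.curate(aln, block_params)
    seqio.write_alignment(curated, out / "curated.fasta")
    with open(out / "kept_columns.txt", "w") as fh:
        fh.write("\n".join(str(i) for i in mask.kept) + "\n")
    with open(out / "blocks.txt", "w") as fh:
        fh.write(blocks.block_report(mask) + "\n")
    dm = trees.distance_matrix(curated, phylo_params.correction,
                               phylo_params.gamma_shape_reference)
    with open(out / "distances.phylip", "w") as fh:
        fh.write(dm.to_phylip())
    tree = trees.bootstrap(curated, phylo_params)
    newick_path = out / "tree.nwk"
    newick_path.write_text(trees.to_newick(tree))
    if calls_tsv is not None:
        families = load_family_calls(calls_tsv)
        leaf_labels = {lf.taxon.label for lf in tree.seed_node.leaf_iter()}
        called = {l: f for l, f in families.items() if l in leaf_labels}
        if len(called) >= 3 and len(called) < len(leaf_labels):
            tree = tree.extract_tree_with_taxa_labels(labels=sorted(called))
        report = trees.monophyly_report(tree, called)
        (out / "monophyly.tsv").write_text(trees.monophyly_table(report))
    return newick_path


def load_family_calls(calls_tsv) -> dict[str, str]:
    """Leaf -> family map from a reclassification TSV (indeterminate dropped)."""
    families = {}
    lines = Path(calls_tsv).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    acc_i = header.index("Accession")
    prop_i = header.index("Proposed name")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        fields = ln.split("\t")
        name = fields[prop_i].replace("(f)", "").replace("(?)", "").rstrip("?")
        if name in ("", "Pax", "no-PRD"):
            continue
        families[fields[acc_i]] = name
    return families


def run_simulate(config: synthetic.SyntheticConfig, out_dir) -> tuple[Path, Path]:
    """Generate a labeled synthetic dataset (FASTA + truth TSV)."""
    out = _outdir(out_dir)
    log.info("simulate config: %s", config)
    records, truths = synthetic.generate_dataset(config)
    fasta = out / "synthetic.fasta"
    seqio.write_fasta(records, fasta)
    truth = out / "truth.tsv"
    synthetic.write_truth_tsv(truths, truth)
    return fasta, truth


def run_all(config: synthetic.SyntheticConfig, out_dir,
            block_params: Optional[blocks.BlockFilterParams] = None,
            phylo_params: Optional[trees.PhyloParams] = None) -> Path:
    """simulate → classify → PRD alignment → curation/tree/monophyly."""
    out = _outdir(out_dir)
    fasta, _ = run_simulate(config, out)
    calls_tsv = run_classify(fasta, out)
    records, truths = synthetic.generate_dataset(config)
    aln = synthetic.prd_alignment(records, truths)
    aligned = out / "prd_alignment.fasta"
    seqio.write_alignment(aln, aligned)
    phylo_params = phylo_params or trees.PhyloParams(seed=config.seed + BOOTSTRAP_SEED_OFFSET)
    return run_tree(aligned, out, block_params, phylo_params, calls_tsv=calls_tsv)
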