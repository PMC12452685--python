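"""End-to-end orchestration: filter -> align -> tree -> clusters -> motifs -> reports.

Stages run in a fixed order, each writing its outputs before the next starts;
a JSON manifest records every parameter, record count and output checksum, so
a rerun with the same config reproduces identical hashes.  A stage failure is
recorded in the manifest and downstream stages are not run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import architecture as arch
from . import conservation, motifs, phylogeny, seqio
from .distances import estimate_distances
from .filtering import FilterConfig, exclude_by_keywords, identity_band_filter, length_filter
from .msa import progressive_align


@dataclass
class PipelineConfig:
    fasta: str
    reference: str
    out_dir: str
    taxonomy_tsv: str | None = None
    regions_tsv: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    k_clusters: int = 10
    n_supergroups: int = 4
    min_score: int = 9
    min_freq: float = 0.80
    max_wildcard_run: int = 3
    min_length: int = 6
    min_anchors: int = 3
    focus_subtype: str = "(D-) amino acid dehydrogenase"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    for path in (config.fasta, config.reference, config.taxonomy_tsv, config.regions_tsv):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(asdict(config)), "stages": []}

    def record_stage(name, params, n_in, n_out, outputs):
        manifest["stages"].append(
            {
                "name": name,
                "status": "ok",
                "params": _jsonable(params),
                "n_in": n_in,
                "n_out": n_out,
                "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            }
        )

    state: dict = {}
    try:
        _run_stages(config, out, state, record_stage)
    except Exception as exc:
        manifest["stages"].append({"name": state.get("stage", "unknown"),
                                   "status": "failed", "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, int, float, bool)):
        return _jsonable(vars(obj))
    return obj


def _run_stages(config: PipelineConfig, out: Path, state: dict, record_stage) -> None:
    fc = config.filter

    state["stage"] = "read"
    taxonomy = (
        seqio.TaxonomyTable.from_tsv(config.taxonomy_tsv)
        if config.taxonomy_tsv
        else seqio.TaxonomyTable.synthetic_default()
    )
    records = seqio.read_annotated_fasta(config.fasta, taxonomy=taxonomy)
    reference = seqio.read_annotated_fasta(config.reference, taxonomy=taxonomy)[0]
    record_stage("read", {"fasta": config.fasta}, len(records), len(records), [])

    state["stage"] = "filter"
    kept, dropped_kw = exclude_by_keywords(records, fc)
    n0 = len(kept)
    kept_len = length_filter(kept, fc)
    kept_final, identities = identity_band_filter(kept_len, reference, fc, return_identities=True)
    dropped_path = out / "dropped.tsv"
    with open(dropped_path, "w") as fh:
        fh.write("accession\tstage\treason\n")
        for rec, kw in dropped_kw:
            fh.write(f"{rec.accession}\tkeyword\t{kw}\n")
        for rec in kept:
            if rec not in kept_len:
                fh.write(f"{rec.accession}\tlength\t{len(rec)}\n")
        for rec in kept_len:
            if rec not in kept_final:
                fh.write(f"{rec.accession}\tidentity\t{identities[rec.accession]:.4f}\n")
    kept_path = out / "kept.fa"
    seqio.write_fasta(kept_final, kept_path)
    record_stage(
        "filter",
        {"min_len": fc.min_len, "max_len": fc.max_len,
         "min_identity": fc.min_identity, "max_identity": fc.max_identity,
         "keywords": list(fc.exclusion_keywords),
         "counts": {"keyword_kept": n0, "length_kept": len(kept_len)}},
        len(records), len(kept_final), [kept_path],
    )

    state["stage"] = "tree"
    dm = estimate_distances(kept_final, fc.matrix, fc.gap_open, fc.gap_extend)
    tree = phylogeny.upgma(dm)
    tree_path = out / "tree.nwk"
    tree_path.write_text(phylogeny.to_newick(tree) + "\n")
    record_stage("tree", {"method": "UPGMA", "distance": "1-identity"},
                 len(kept_final), len(kept_final), [tree_path])

    state["stage"] = "clusters"
    k = min(config.k_clusters, len(kept_final))
    assignment = phylogeny.cut_clusters(tree, k)
    groups = phylogeny.supergroup_clusters(tree, assignment, min(config.n_supergroups, k))
    clusters_path = out / "clusters.tsv"
    with open(clusters_path, "w") as fh:
        fh.write("accession\tcluster\tgroup\n")
        for acc in sorted(assignment.assignment):
            cid = assignment.assignment[acc]
            fh.write(f"{acc}\t{cid}\t{groups[cid]}\n")
    record_stage("clusters", {"k": k, "n_supergroups": min(config.n_supergroups, k)},
                 len(kept_final), k, [clusters_path])

    state["stage"] = "align"
    msa = progressive_align(kept_final, guide=tree, matrix=fc.matrix,
                            gap_open=fc.gap_open, gap_extend=fc.gap_extend)
    msa_path = out / "msa.afa"
    msa.to_fasta(msa_path)
    record_stage("align", {"matrix": fc.matrix, "gap_open": fc.gap_open,
                           "gap_extend": fc.gap_extend},
                 len(kept_final), msa.n_rows, [msa_path])

    state["stage"] = "motifs"
    track = conservation.profile_columns(msa)
    found = motifs.extract_motifs(
        track, config.min_score, config.min_freq,
        config.max_wildcard_run, config.min_length, config.min_anchors,
    )
    prm = motifs.detect_prm(track, config.min_freq)
    track_path = out / "conservation.tsv"
    track.to_dataframe().to_csv(track_path, sep="\t", index=False)
    motifs_path = out / "motifs.tsv"
    with open(motifs_path, "w") as fh:
        fh.write("name\tstart\tend\tpattern\n")
        for p in found:
            fh.write(f"{p.name}\t{p.start_column}\t{p.end_column}\t{p.render()}\n")
        if prm.proline_columns:
            fh.write(
                f"PRM\t{prm.proline_columns[0]}\t{prm.proline_columns[-1]}\t{prm.composite}\n"
            )
    record_stage("motifs", {"min_score": config.min_score, "min_freq": config.min_freq},
                 msa.column_count, len(found), [track_path, motifs_path])

    if config.regions_tsv:
        state["stage"] = "architecture"
        regions = arch.load_regions(config.regions_tsv, kept_final)
        kept_accs = {r.accession for r in kept_final}
        regions = [r for r in regions if r.accession in kept_accs]
        labels = arch.classify_all(regions, kept_final)
        arch_path = out / "architecture.tsv"
        with open(arch_path, "w") as fh:
            fh.write("accession\tgroup\n")
            for acc in sorted(labels):
                fh.write(f"{acc}\t{labels[acc]}\n")
        record_stage("architecture", {}, len(kept_final), len(set(labels.values())), [arch_path])

    state["stage"] = "report"
    onto = seqio.ontology_report(kept_final)
    rank_df, class_df = seqio.taxonomy_report(kept_final)
    comp = phylogeny.cluster_composition(assignment, kept_final, subtype=config.focus_subtype)
    onto_path = out / "ontology_report.tsv"
    onto.to_csv(onto_path, sep="\t", index=False)
    tax_path = out / "taxonomy_report.tsv"
    rank_df.to_csv(tax_path, sep="\t", index=False)
    comp_path = out / "cluster_composition.tsv"
    comp["class_counts"].to_csv(comp_path, sep="\t")
    record_stage(
        "report",
        {"focus_subtype": config.focus_subtype,
         "subtype_median": comp.get("subtype_median")},
        len(kept_final), len(onto), [onto_path, tax_path, comp_path],
    )
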