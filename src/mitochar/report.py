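"""The combined characterization run: every stage over one genome, written
as deterministic TSV/JSON reports plus a hashed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import composition, genemap, repeats, trna
from .io import AnnotatedGenome, write_reports

log = logging.getLogger("mitochar")


@dataclass
class RunConfig:
    outdir: Path
    genetic_code: int = 2
    repeat_min_period: int = 10
    repeat_max_period: int = 200
    repeat_min_copies: float = 2.0
    repeat_max_mismatch_frac: float = 0.2
    palindrome_min_len: int = 6
    palindrome_mode: str = "inverted"
    palindrome_max_loop: int = 0
    dnds_method: str = "tree_parsimony"
    bootstrap: int = 1000
    seed: int = 0
    structures_path: Path | None = None
    skew_precision: int = 3
    dnds_precision: int = 4
    extra: dict = field(default_factory=dict)


def characterize(genome: AnnotatedGenome, config: RunConfig) -> dict:
    """Run gene-map, composition, codon, repeat and (optionally) tRNA stages.

    Stages needing sequence are skipped, and listed as skipped, when the
    genome is coordinate-only.  Returns the manifest (also written as
    manifest.json): every artifact with a content hash, plus the skip list.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    skipped: list[str] = []

    def stage(name, fn):
        try:
            fn()
            log.info("stage %s done", name)
        except Exception:
            log.error("stage %s failed", name)
            raise

    def _genemap():
        profile = genemap.intergenic_profile(genome)
        artifacts.update(
            {"adjacency_" + k: v
             for k, v in write_reports(genemap.profile_table(profile), outdir, "adjacency").items()}
        )
        summary = genemap.summarize_gene_map(genome)
        payload = {
            "overlap_count": summary.overlap_count,
            "overlap_total_bp": summary.overlap_total_bp,
            "longest_overlap": summary.longest_overlap,
            "spacer_count": summary.spacer_count,
            "spacer_total_bp": summary.spacer_total_bp,
            "longest_spacer": summary.longest_spacer,
            "coverage_fraction": summary.coverage_fraction,
            "coverage_fraction_union": summary.coverage_fraction_union,
            "strand_counts": {f"{c}/{s}": n for (c, s), n in sorted(summary.strand_counts.items())},
            "circular_closure_gap": summary.circular_closure_gap,
            "n_feature_instances": genome.n_feature_instances,
            "n_unique_gene_names": genome.unique_gene_names,
        }
        path = outdir / "genemap_summary.json"
        path.write_text(json.dumps(payload, indent=1, default=list) + "\n")
        artifacts["genemap_summary"] = path

    stage("genemap", _genemap)

    if genome.sequence:
        def _composition():
            rows = [composition.composition_summary(genome.sequence, "whole_genome")]
            for cls in ("PCG", "rRNA", "tRNA", "control_region"):
                try:
                    rows += composition.region_composition(genome, cls)
                except ValueError:
                    pass
            artifacts.update(
                {"composition_" + k: v
                 for k, v in write_reports(
                     composition.summary_table(rows), outdir, "composition",
                     precision=config.skew_precision).items()}
            )

        def _codons():
            cds = {
                f.instance_id: composition.trim_stop(genome.feature_sequence(f))
                for f in genome.select("PCG")
            }
            usage = composition.codon_usage(cds, config.genetic_code)
            df = pd.DataFrame(
                sorted((c, usage.counts[c], usage.rscu[c]) for c in usage.counts),
                columns=["codon", "count", "rscu"],
            )
            artifacts.update(
                {"rscu_" + k: v for k, v in write_reports(df, outdir, "rscu").items()}
            )
            aa = pd.DataFrame(
                sorted(usage.aa_frequencies.items()), columns=["aa", "frequency"]
            )
            artifacts.update(
                {"aa_" + k: v for k, v in write_reports(aa, outdir, "aa_frequencies").items()}
            )
            bounds = composition.classify_codon_boundaries(genome)
            artifacts.update(
                {"boundaries_" + k: v
                 for k, v in write_reports(bounds, outdir, "codon_boundaries").items()}
            )

        def _repeats():
            hits = repeats.find_tandem_repeats(
                genome.sequence,
                config.repeat_min_period, config.repeat_max_period,
                config.repeat_min_copies, config.repeat_max_mismatch_frac,
            )
            artifacts.update(
                {"repeats_" + k: v for k, v in write_reports(hits, outdir, "tandem_repeats").items()}
            )
            pals = repeats.find_palindromes(
                genome.sequence, config.palindrome_min_len,
                config.palindrome_mode, config.palindrome_max_loop,
            )
            artifacts.update(
                {"palindromes_" + k: v for k, v in write_reports(pals, outdir, "palindromes").items()}
            )

        stage("composition", _composition)
        stage("codons", _codons)
        stage("repeats", _repeats)
    else:
        skipped += ["composition", "codons", "repeats"]
        log.warning("no sequence: coordinate-only subset produced (skipped: %s)", skipped)

    if config.structures_path:
        def _trna():
            structures = trna.read_structures(config.structures_path)
            rep = trna.pair_type_report(structures)
            total, n_genes, per_stem = trna.aggregate_mismatches(rep)
            df = pd.DataFrame(rep.mismatch_detail, columns=["gene", "pair", "stem"])
            artifacts.update(
                {"trna_" + k: v for k, v in write_reports(df, outdir, "trna_mismatches").items()}
            )
            summary = outdir / "trna_summary.json"
            summary.write_text(json.dumps(
                {"total_mismatches": total, "genes_with_mismatch": n_genes,
                 "per_stem": per_stem}, indent=1) + "\n")
            artifacts["trna_summary"] = summary

        stage("trna", _trna)
    else:
        skipped.append("trna")

    manifest = {
        "accession": genome.accession,
        "seed": config.seed,
        "skipped_stages": skipped,
        "artifacts": {
            name: {
                "path": str(path.relative_to(outdir)),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for name, path in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


__all__ = ["RunConfig", "characterize"]
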