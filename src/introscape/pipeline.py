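"""Config-driven orchestration of the full analysis.

A run reads a TOML config naming the inputs (VCF, popmap, CDS intervals,
guide tree, optional gene trees and CDS alignment), executes the enabled
stages in order — filter, windows, diversity, introgression, discordance,
LOF, landscape — and writes one TSV per result table plus a JSON manifest
recording seeds, filter bookkeeping and output checksums.  Re-running the
same config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tomllib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diversity as div
from . import introgression as intro
from . import io as iio
from . import landscape as land
from . import lof as lof_mod
from . import windows as win
from .core import PopulationMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    out_dir: str
    guide_tree: str | None = None
    outgroup: str | None = None
    gff: str | None = None
    bed: str | None = None
    gene_trees: str | None = None
    cds_alignment: str | None = None
    cds_reference: str | None = None
    bp_window_sizes: list[int] = field(default_factory=lambda: [10_000, 50_000])
    snp_window_size: int = 500
    snp_window_slide: int = 125
    min_qual: float | None = 20.0
    min_dp: int | None = 3
    max_dp: int | None = 60
    min_gt_dp: int | None = 2
    max_missing: float = 0.5
    n_jackknife_blocks: int = 20
    outlier_z: float = 3.0
    alpha: float = 0.05
    large_deletion_min: int = 100
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: [
            "filter", "windows", "diversity", "introgression", "discordance",
            "lof", "landscape",
        ]
    )

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - fields
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"config incomplete: {exc}") from exc
        return cfg

    def validate(self) -> None:
        for name in ("vcf", "popmap"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise ValidationError(f"config field {name!r}: missing file {path!r}")
        for name in ("guide_tree", "gff", "bed", "gene_trees", "cds_alignment"):
            path = getattr(self, name)
            if path and not os.path.exists(path):
                raise ValidationError(f"config field {name!r}: missing file {path!r}")

    def filter_config(self) -> iio.FilterConfig:
        return iio.FilterConfig(
            min_site_quality=self.min_qual,
            min_site_depth=self.min_dp,
            max_site_depth=self.max_dp,
            min_genotype_depth=self.min_gt_dp,
            max_site_missingness=self.max_missing,
        )


def _taxon_level(tree, popmap: PopulationMap):
    """Prune a sample-level tree to one tip per population (the
    lexicographically smallest sample) and relabel tips to populations."""
    import dendropy

    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    reps = {}
    for pop in popmap.populations:
        present = sorted(s for s in popmap.samples(pop) if s in tips)
        if present:
            reps[present[0]] = pop
    sub = tree.extract_tree_with_taxa_labels(list(reps))
    nwk = sub.as_string(schema="newick", suppress_rooting=True)
    pruned = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    for leaf in pruned.leaf_node_iter():
        leaf.taxon.label = reps[leaf.taxon.label]
    return pruned


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}, "counts": {}}
    stage = "filter"
    try:
        matrix, stats = iio.read_vcf(config.vcf, config.filter_config())
        popmap = PopulationMap.from_tsv(config.popmap)
        manifest["counts"]["filter"] = stats.as_dict()
        manifest["stages"]["filter"] = "ok"

        cds = {}
        if config.bed:
            cds = iio.read_intervals(config.bed, "BED")
        elif config.gff:
            cds = iio.read_intervals(config.gff, "GFF3")

        guide = None
        if config.guide_tree:
            guide = iio.read_trees(config.guide_tree)[0]

        scaffold_lengths = {
            name: int(matrix.positions[matrix.scaffold_index == i].max())
            for i, name in enumerate(matrix.scaffold_names)
        }

        windows_by_size = {}
        snp_windows = []
        if "windows" in config.stages:
            stage = "windows"
            for size in config.bp_window_sizes:
                ws = win.bp_windows(scaffold_lengths, size)
                win.annotate_genic_fraction(ws, cds)
                windows_by_size[size] = ws
                path = os.path.join(config.out_dir, f"windows_{size}bp.tsv")
                _write_tsv(pd.DataFrame(win.windows_to_rows(ws)), path)
                manifest["outputs"][f"windows_{size}bp"] = path
            snp_windows = win.snp_windows(
                matrix, config.snp_window_size, config.snp_window_slide
            )
            win.annotate_genic_fraction(snp_windows, cds)
            path = os.path.join(config.out_dir, "windows_snp.tsv")
            _write_tsv(pd.DataFrame(win.windows_to_rows(snp_windows)), path)
            manifest["outputs"]["windows_snp"] = path
            manifest["stages"]["windows"] = "ok"

        if "diversity" in config.stages and windows_by_size:
            stage = "diversity"
            size0 = config.bp_window_sizes[0]
            table = div.diversity_table(matrix, popmap, windows_by_size[size0])
            path = os.path.join(config.out_dir, "diversity.tsv")
            _write_tsv(table, path)
            manifest["outputs"]["diversity"] = path
            # dxy outlier windows per population pair
            dxy = table[table["statistic"] == "dxy"]
            outl_rows = []
            for pair, sub in dxy.groupby("populations"):
                recs = [
                    div.DiversityRecord(
                        window=win.Window(
                            scaffold=r.scaffold, start=int(r.start), end=int(r.end)
                        ),
                        statistic="dxy",
                        populations=tuple(pair.split("/")),
                        sum_diffs=r.sum_diffs,
                        sum_comparisons=r.sum_comparisons,
                        sum_missing=r.sum_missing,
                        value=r.value,
                    )
                    for r in sub.itertuples()
                ]
                try:
                    outliers = div.dxy_outliers(recs, config.outlier_z)
                except ValidationError:
                    continue
                for key in sorted(outliers):
                    outl_rows.append(
                        {"populations": pair, "scaffold": key[0],
                         "start": key[1], "end": key[2]}
                    )
            path = os.path.join(config.out_dir, "dxy_outliers.tsv")
            _write_tsv(pd.DataFrame(outl_rows), path)
            manifest["outputs"]["dxy_outliers"] = path
            manifest["stages"]["diversity"] = "ok"

        fdm_tables = {}
        if "introgression" in config.stages and guide is not None and config.outgroup:
            stage = "introgression"
            trios = intro.all_trio_tests(
                matrix, popmap, guide, config.outgroup,
                n_blocks=config.n_jackknife_blocks, alpha=config.alpha,
            )
            trio_df = pd.DataFrame(
                [
                    {"P1": r.p1, "P2": r.p2, "P3": r.p3, "outgroup": r.outgroup,
                     "D": r.d, "Z": r.z, "p": r.p_value, "f4_ratio": r.f4_ratio,
                     "n_sites": r.n_sites_used, "significant": r.significant}
                    for r in trios
                ]
            )
            path = os.path.join(config.out_dir, "trios.tsv")
            _write_tsv(trio_df, path)
            manifest["outputs"]["trios"] = path
            if snp_windows:
                for r in trios:
                    pops = (r.p1, r.p2, r.p3, config.outgroup)
                    table = intro.fdm_windows(matrix, popmap, pops, snp_windows)
                    fdm_tables[pops[:3]] = table
                    name = f"fdm_{r.p1}_{r.p2}_{r.p3}"
                    path = os.path.join(config.out_dir, name + ".tsv")
                    _write_tsv(table, path)
                    manifest["outputs"][name] = path
            fb = intro.f_branch(
                guide, matrix, popmap, config.outgroup,
                n_blocks=config.n_jackknife_blocks,
            )
            path = os.path.join(config.out_dir, "fbranch.tsv")
            fb.to_dataframe().to_csv(path, sep="\t", float_format="%.8g", na_rep="NA")
            manifest["outputs"]["fbranch"] = path
            manifest["stages"]["introgression"] = "ok"

        if "discordance" in config.stages and config.gene_trees and guide is not None:
            stage = "discordance"
            from . import discordance as disc

            gene_trees = iio.read_trees(config.gene_trees)
            guide_tips = {l.taxon.label for l in guide.leaf_node_iter()}
            tree_tips = (
                {l.taxon.label for l in gene_trees[0].leaf_node_iter()}
                if gene_trees
                else set()
            )
            if guide_tips.isdisjoint(tree_tips):
                # sample-level window trees vs a taxon-level guide: prune
                # each window tree to one representative sample per
                # population and relabel it to the population
                gene_trees = [_taxon_level(t, popmap) for t in gene_trees]
            rows = []
            for i, gt in enumerate(gene_trees):
                try:
                    rows.append({"tree": i, "rf": disc.rf_normalized(gt, guide)})
                except ValidationError:
                    rows.append({"tree": i, "rf": float("nan")})
            path = os.path.join(config.out_dir, "rf.tsv")
            _write_tsv(pd.DataFrame(rows), path)
            manifest["outputs"]["rf"] = path
            gcf = disc.gene_concordance(gene_trees, guide)
            path = os.path.join(config.out_dir, "gcf.tsv")
            _write_tsv(
                pd.DataFrame(
                    [
                        {"branch": ",".join(sorted(r.branch)), "gCF": r.gcf,
                         "n_decisive": r.gcf_n_decisive}
                        for r in gcf
                    ]
                ),
                path,
            )
            manifest["outputs"]["gcf"] = path
            manifest["stages"]["discordance"] = "ok"

        if "lof" in config.stages and config.cds_alignment and config.cds_reference:
            stage = "lof"
            aln = lof_mod.CdsAlignmentSet.from_fasta(
                config.cds_alignment, config.cds_reference
            )
            reports, shared = lof_mod.classify(aln, config.large_deletion_min)
            path = os.path.join(config.out_dir, "lof_reports.tsv")
            _write_tsv(pd.DataFrame(lof_mod.reports_to_rows(reports)), path)
            manifest["outputs"]["lof_reports"] = path
            path = os.path.join(config.out_dir, "lof_shared.tsv")
            _write_tsv(
                pd.DataFrame(
                    [
                        {"kind": k[0], "position": k[1], "length": k[2],
                         "samples": ",".join(v)}
                        for k, v in sorted(shared.items())
                    ]
                ),
                path,
            )
            manifest["outputs"]["lof_shared"] = path
            manifest["stages"]["lof"] = "ok"

        if "landscape" in config.stages and fdm_tables:
            stage = "landscape"
            rows = []
            for trio, table in fdm_tables.items():
                try:
                    reg = land.regress(table, "fdm")
                except ValidationError as exc:
                    logger.warning("regression skipped for %s: %s", trio, exc)
                    continue
                rows.append(
                    {"trio": "_".join(trio), "slope": reg.slope,
                     "intercept": reg.intercept, "r_squared": reg.r_squared,
                     "p": reg.p_value, "n_windows": reg.n_windows}
                )
            path = os.path.join(config.out_dir, "landscape.tsv")
            _write_tsv(pd.DataFrame(rows), path)
            manifest["outputs"]["landscape"] = path
            manifest["stages"]["landscape"] = "ok"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["checksums"] = {
        name: _checksum(path) for name, path in manifest["outputs"].items()
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
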