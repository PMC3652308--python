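"""End-to-end orchestration: demo bundle generation and the full run.

The full run executes quantification -> differential expression (three
contrasts) -> splice calling (two contrasts) -> enrichment -> lineage
scoring -> network assembly -> sample classification, writing every
artifact as TSV/JSON plus a manifest of all parameters, seeds and record
counts.  All stages are deterministic under the global seed.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (
    diffexp,
    enrichment,
    lineage,
    network,
    smallrna_quant,
    splicing,
    synthetic_data,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "make_demo", "run_all"]

DE_CONTRASTS = synthetic_data.CONTRASTS
SPLICE_CONTRASTS = (("HC", "PD"), ("PD", "DBS_ON"))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for a full run.

    Threshold defaults follow the study's stated gates: CPM >= 1 in >= 3
    libraries, B >= 1, splice fold change 2 at p < 0.05, splicing index 1
    log2 unit, ORA z >= 1.96 with >= 3 changed genes and 2000
    permutations.
    """

    reads_dir: str = ""
    reference_map: str = ""
    filter_map: str = ""
    design_table: str = ""
    probe_matrix: str = ""
    probe_annotations: str = ""
    probe_design: str = ""
    gene_sets: str = ""
    compendium: str = ""
    compendium_labels: str = ""
    lineage_samples: str = ""
    target_table: str = ""
    independent_matrix: str = ""
    independent_labels: str = ""
    out_dir: str = "results"
    min_cpm: float = 1.0
    min_libraries: int = 3
    b_threshold: float = 1.0
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    si_threshold: float = 1.0
    z_cutoff: float = 1.96
    min_genes: int = 3
    n_perm: int = 2000
    markers_per_lineage: int = 60
    seed: int = 0
    de_contrasts: list = field(default_factory=lambda: [list(c) for c in DE_CONTRASTS])
    splice_contrasts: list = field(
        default_factory=lambda: [list(c) for c in SPLICE_CONTRASTS]
    )

    def __post_init__(self) -> None:
        for name in (
            "min_cpm",
            "b_threshold",
            "fc_threshold",
            "p_threshold",
            "si_threshold",
            "z_cutoff",
        ):
            if getattr(self, name) <= 0 and name != "min_cpm":
                raise ValueError(f"threshold {name} must be positive")
        valid = {tuple(c) for c in synthetic_data.CONTRASTS}
        for c in [*self.de_contrasts, *self.splice_contrasts]:
            if tuple(c) not in valid:
                raise ValueError(f"contrast {c} not drawn from the four-condition design")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def make_demo(seed: int = 0, out_dir="demo_inputs", scale: float = 1.0) -> PipelineConfig:
    """Write a complete synthetic input bundle plus truth files.

    ``scale`` multiplies the sequencing depth and gene counts for larger
    smoke tests; the default bundle runs the whole pipeline in well under
    a minute.  Returns a ready-to-run configuration (also written to
    ``config.yaml`` in the bundle).
    """
    rng_master = np.random.default_rng(seed)
    sub = [int(s) for s in rng_master.integers(0, 2**31 - 1, size=8)]
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref = synthetic_data.generate_mirna_reference(
        n_mirnas=40, n_star=8, seed=sub[0], n_shared=2
    )
    mature_ids = sorted(ref.mature_sequences())
    planted = {
        mature_ids[1]: (("HC", "PD"), 2.0),
        mature_ids[3]: (("HC", "PD"), -2.0),
        mature_ids[5]: (("PD", "DBS_ON"), 2.0),
        mature_ids[7]: (("DBS_ON", "DBS_OFF"), -2.0),
    }
    design = synthetic_data.StudyDesign(
        libraries_per_condition=3, planted_de=planted, seed=sub[1]
    )
    readset = synthetic_data.simulate_reads(
        ref, design, mean_depth=int(1500 * scale), phi=0.1, seed=sub[1]
    )
    readset.write_fastq(out / "reads")
    ref.write_map(out / "mirna_reference.tsv")
    filter_ref = synthetic_data.generate_mirna_reference(
        n_mirnas=12, n_star=0, seed=sub[2], n_shared=0
    )
    filter_ref.write_map(out / "filter_reference.tsv")
    design.groups().to_csv(out / "design.tsv", sep="\t", index_label="library")
    readset.truth_counts.to_csv(out / "truth_counts.tsv", sep="\t", index_label="mature_id")

    n_genes = max(40, int(80 * scale))
    truth = synthetic_data.plant_splice_truth(
        n_genes, n_events=8, contrast=("HC", "PD"), effect=1.5, seed=sub[3]
    )
    truth2 = synthetic_data.plant_splice_truth(
        n_genes, n_events=5, contrast=("PD", "DBS_ON"), effect=1.5, start_gene=8
    )
    truth3 = synthetic_data.plant_splice_truth(
        n_genes, n_events=4, contrast=("HC", "PD"), effect=1.3, exon_level=True,
        start_gene=13,
    )
    truth.events.extend(truth2.events)
    truth.events.extend(truth3.events)
    probe_matrix, truth = synthetic_data.simulate_probe_matrix(
        n_genes, design, truth=truth, noise_sd=0.2, samples_per_condition=6, seed=sub[4]
    )
    probe_matrix.write_tsv(out / "probe_matrix.tsv", out / "probe_annotations.tsv")
    probe_matrix.sample_conditions.to_csv(
        out / "probe_design.tsv", sep="\t", index_label="sample", header=["condition"]
    )
    truth.frame().to_csv(out / "truth_splice.tsv", sep="\t", index=False)

    genes = sorted(probe_matrix.annotations["gene"].unique())
    table = synthetic_data.simulate_target_table(ref, genes, density=3.0, seed=sub[5])
    # plant predictions linking the DE miRNAs to the spliced genes so the
    # assembled networks are non-trivial; planted pairs recorded as truth
    regions = ["3UTR", "CDS", "5UTR"]
    planted_rows = []
    event_genes = sorted({e.gene for e in truth.events})
    for i, mid in enumerate(sorted(planted)):
        for j, gene in enumerate(event_genes[:6]):
            planted_rows.append((mid, gene, regions[(i + j) % 3], 9000 + i * 10 + j))
    planted_table = pd.DataFrame(
        planted_rows, columns=["mirna", "gene", "region", "site_offset"]
    )
    table = (
        pd.concat([table, planted_table], ignore_index=True)
        .drop_duplicates(["mirna", "gene", "region", "site_offset"])
        .reset_index(drop=True)
    )
    table.to_csv(out / "target_table.tsv", sep="\t", index=False)
    planted_table.to_csv(out / "truth_network_pairs.tsv", sep="\t", index=False)
    sets = synthetic_data.simulate_gene_sets(genes, n_sets=15, seed=sub[5])
    # one genuinely enriched set: the spliced genes plus a little padding
    other = [g for g in genes if g not in event_genes]
    sets["SET_SPLICED"] = sorted(event_genes + other[:3])
    enrichment.GeneSetCollection(sets=sets, background=genes).to_gmt(out / "gene_sets.gmt")

    comp, labels, ltruth = synthetic_data.simulate_lineage_compendium(
        n_lineages=4, markers_per_lineage=60, n_samples=3, seed=sub[6]
    )
    comp.to_csv(out / "compendium.tsv", sep="\t", index_label="gene")
    labels.to_csv(out / "compendium_labels.tsv", sep="\t", index_label="sample")
    mixtures, dominant = synthetic_data.simulate_mixture_samples(
        ltruth["profiles"],
        {"lineage_A": 0.9, "lineage_B": 0.1},
        n_samples=12,
        seed=sub[6],
    )
    mixtures.to_csv(out / "lineage_samples.tsv", sep="\t", index_label="gene")
    dominant.to_csv(out / "truth_dominant_lineage.tsv", sep="\t", index_label="sample")

    indep, ilabels = synthetic_data.simulate_twogroup_matrix(
        n_features=int(100 * scale), group_sizes=(12, 12), effect=2.0, seed=sub[7]
    )
    indep.to_csv(out / "independent_matrix.tsv", sep="\t", index_label="feature")
    ilabels.to_csv(out / "independent_labels.tsv", sep="\t", index_label="sample")

    cfg = PipelineConfig(
        reads_dir=str(out / "reads"),
        reference_map=str(out / "mirna_reference.tsv"),
        filter_map=str(out / "filter_reference.tsv"),
        design_table=str(out / "design.tsv"),
        probe_matrix=str(out / "probe_matrix.tsv"),
        probe_annotations=str(out / "probe_annotations.tsv"),
        probe_design=str(out / "probe_design.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        compendium=str(out / "compendium.tsv"),
        compendium_labels=str(out / "compendium_labels.tsv"),
        lineage_samples=str(out / "lineage_samples.tsv"),
        target_table=str(out / "target_table.tsv"),
        independent_matrix=str(out / "independent_matrix.tsv"),
        independent_labels=str(out / "independent_labels.tsv"),
        out_dir=str(out / "results"),
        n_perm=500,
        markers_per_lineage=60,
        seed=seed,
    )
    cfg.to_yaml(out / "config.yaml")
    return cfg


def _read_fastq_dir(reads_dir) -> dict[str, list[tuple[str, str]]]:
    from Bio import SeqIO

    reads_dir = pathlib.Path(reads_dir)
    if not reads_dir.is_dir():
        raise FileNotFoundError(f"reads directory not found: {reads_dir}")
    out = {}
    for path in sorted(reads_dir.glob("*.fastq")):
        out[path.stem] = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")
        ]
    if not out:
        raise FileNotFoundError(f"no FASTQ files under {reads_dir}")
    return out


def _require(path: str, what: str) -> str:
    if not path or not pathlib.Path(path).exists():
        raise FileNotFoundError(f"{what} not found: {path!r}")
    return path


def run_quant(cfg: PipelineConfig):
    reads = _read_fastq_dir(cfg.reads_dir)
    ref = synthetic_data.MiRNAReference.read_map(_require(cfg.reference_map, "reference map"))
    trimmed = {
        lib: smallrna_quant.trim_reads(recs).reads for lib, recs in reads.items()
    }
    matrix, unmapped, stats = smallrna_quant.align_and_count(trimmed, ref)
    if cfg.filter_map and pathlib.Path(cfg.filter_map).exists():
        filter_ref = synthetic_data.MiRNAReference.read_map(cfg.filter_map)
        _fm, _un, fstats = smallrna_quant.align_filter_db(unmapped, filter_ref)
    else:
        fstats = None
    merged = smallrna_quant.merge_counts(matrix)
    merged.norm_factors = diffexp.norm_factors(merged)
    filtered = smallrna_quant.cpm_filter(merged, cfg.min_cpm, cfg.min_libraries)
    return filtered, stats, fstats


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the result bundle and writes artifacts."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "min_cpm": config.min_cpm,
            "min_libraries": config.min_libraries,
            "b_threshold": config.b_threshold,
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "si_threshold": config.si_threshold,
            "z_cutoff": config.z_cutoff,
            "min_genes": config.min_genes,
            "n_perm": config.n_perm,
            "markers_per_lineage": config.markers_per_lineage,
        },
        "stages": {},
    }

    # --- quantification -------------------------------------------------
    try:
        counts, map_stats, filter_stats = run_quant(config)
        groups = pd.read_csv(
            _require(config.design_table, "design table"), sep="\t", index_col="library"
        )["condition"]
        counts.counts.to_csv(out / "counts.tsv", sep="\t", index_label="feature")
        map_stats.to_csv(out / "mapping_stats.tsv", sep="\t")
        if filter_stats is not None:
            filter_stats.to_csv(out / "filter_mapping_stats.tsv", sep="\t")
        bundle["counts"] = counts
        manifest["stages"]["quant"] = {
            "features_after_cpm_filter": int(counts.counts.shape[0]),
            "libraries": int(counts.counts.shape[1]),
            "total_mapped": int(map_stats["mapped"].sum()),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("quant", exc) from exc

    # --- differential expression ---------------------------------------
    try:
        phi = diffexp.estimate_common_dispersion(counts, groups)
        de_tables = {}
        for c1, c2 in [tuple(c) for c in config.de_contrasts]:
            libs = groups.index[groups.isin([c1, c2])]
            sub = smallrna_quant.CountMatrix(
                counts=counts.counts[libs],
                annotations=counts.annotations,
                norm_factors=counts.norm_factors[libs],
            )
            tab = diffexp.de_table(
                sub,
                groups[libs],
                dispersion=diffexp.DispersionModel(phi),
                b_threshold=config.b_threshold,
            )
            name = f"{c1}-vs-{c2}"
            tab.to_csv(out / f"de_{name}.tsv", sep="\t", index_label="feature")
            de_tables[(c1, c2)] = tab
        bundle["de"] = de_tables
        manifest["stages"]["diffexp"] = {
            "common_dispersion": round(float(phi), 6),
            "calls": {
                f"{c1}-vs-{c2}": int(t["called"].sum())
                for (c1, c2), t in de_tables.items()
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diffexp", exc) from exc

    # --- splicing -------------------------------------------------------
    try:
        probe_groups = pd.read_csv(
            _require(config.probe_design, "probe design table"),
            sep="\t",
            index_col="sample",
        )["condition"]
        matrix = splicing.ProbeSetMatrix.read_tsv(
            _require(config.probe_matrix, "probe matrix"),
            _require(config.probe_annotations, "probe annotations"),
            sample_conditions=probe_groups,
        )
        summary = splicing.summarize_gene_expression(matrix)
        junction_events, si_events = {}, {}
        for c1, c2 in [tuple(c) for c in config.splice_contrasts]:
            name = f"{c1}-vs-{c2}"
            jev = splicing.detect_junction_events(
                matrix,
                summary,
                (c1, c2),
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
            )
            sev = splicing.detect_splicing_index_events(
                matrix,
                summary,
                (c1, c2),
                si_threshold=config.si_threshold,
                p_threshold=config.p_threshold,
            )
            jev.to_csv(out / f"junction_events_{name}.tsv", sep="\t", index=False)
            sev.to_csv(out / f"splicing_index_events_{name}.tsv", sep="\t", index=False)
            junction_events[(c1, c2)] = jev
            si_events[(c1, c2)] = sev
        bundle["splice_matrix"] = matrix
        bundle["junction_events"] = junction_events
        bundle["si_events"] = si_events
        manifest["stages"]["splicing"] = {
            "genes_summarized": int(summary.shape[0]),
            "junction_calls": {
                f"{c1}-vs-{c2}": int(j["called"].sum())
                for (c1, c2), j in junction_events.items()
            },
            "splicing_index_calls": {
                f"{c1}-vs-{c2}": int(s["called"].sum())
                for (c1, c2), s in si_events.items()
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("splicing", exc) from exc

    # --- enrichment -----------------------------------------------------
    try:
        collection = enrichment.GeneSetCollection.from_gmt(
            _require(config.gene_sets, "gene sets GMT")
        )
        enr = {}
        for contrast, jev in junction_events.items():
            changed = sorted(set(jev.loc[jev["called"], "gene"]))
            tab = enrichment.enrich(
                collection, changed, n_perm=config.n_perm, seed=config.seed
            )
            report = enrichment.rank_report(tab, config.z_cutoff, config.min_genes)
            name = f"{contrast[0]}-vs-{contrast[1]}"
            tab.to_csv(out / f"enrichment_{name}.tsv", sep="\t")
            report.to_csv(out / f"enrichment_report_{name}.tsv", sep="\t")
            enr[contrast] = tab
        bundle["enrichment"] = enr
        manifest["stages"]["enrichment"] = {
            "sets": len(collection.sets),
            "reported": {
                f"{c1}-vs-{c2}": int(
                    ((t["z_score"] >= config.z_cutoff) & (t["r"] >= config.min_genes)).sum()
                )
                for (c1, c2), t in enr.items()
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enrichment", exc) from exc

    # --- lineage --------------------------------------------------------
    try:
        comp = pd.read_csv(_require(config.compendium, "compendium"), sep="\t", index_col="gene")
        clabels = pd.read_csv(
            _require(config.compendium_labels, "compendium labels"),
            sep="\t",
            index_col="sample",
        )["lineage"]
        ref = lineage.build_marker_db(comp, clabels, config.markers_per_lineage)
        ref.write_tsv(out / "lineage_markers.tsv")
        lsamples = pd.read_csv(
            _require(config.lineage_samples, "lineage sample matrix"),
            sep="\t",
            index_col="gene",
        )
        r, z = lineage.score_samples(lsamples, ref)
        r.to_csv(out / "lineage_pearson.tsv", sep="\t", index_label="sample")
        z.to_csv(out / "lineage_z.tsv", sep="\t", index_label="sample")
        bundle["lineage_z"] = z
        manifest["stages"]["lineage"] = {
            "lineages": int(z.shape[1]),
            "samples_scored": int(z.shape[0]),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("lineage", exc) from exc

    # --- network --------------------------------------------------------
    try:
        table = pd.read_csv(_require(config.target_table, "target table"), sep="\t")
        mirna_seqs = synthetic_data.MiRNAReference.read_map(
            config.reference_map
        ).mature_sequences()
        probe_seqs = matrix.annotations["sequence"].to_dict()
        networks = {}
        for contrast in [tuple(c) for c in config.splice_contrasts]:
            de_tab = de_tables.get(contrast)
            if de_tab is None:
                continue
            events = pd.concat(
                [junction_events[contrast], si_events[contrast]], ignore_index=True
            )
            net = network.build_network(de_tab, events, table, contrast)
            seed_summary = network.verify_network_seeds(
                net, mirna_seqs, events, probe_seqs
            )
            summary = network.region_distribution(net)
            summary["seed_verification"] = seed_summary
            name = f"{contrast[0]}-vs-{contrast[1]}"
            network.export_network(net, out / f"network_{name}.sif", "SIF")
            network.export_network(net, out / f"network_{name}.graphml", "GraphML")
            with open(out / f"network_summary_{name}.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            networks[contrast] = net
        bundle["networks"] = networks
        manifest["stages"]["network"] = {
            f"{c1}-vs-{c2}": {
                "edges": net.n_edges,
                "mirnas": len(net.mirna_nodes),
                "genes": len(net.gene_nodes),
            }
            for (c1, c2), net in networks.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("network", exc) from exc

    # --- classification -------------------------------------------------
    try:
        reports = {}
        hcpd = tuple(config.splice_contrasts[0])
        jev = junction_events[hcpd]
        features = sorted(jev.loc[jev["called"], "inclusion_probe_set"])
        if features:
            cols = matrix.intensities.columns[
                matrix.sample_conditions.reindex(matrix.intensities.columns).isin(hcpd)
            ]
            res = splicing.classify_samples(
                matrix.intensities[cols],
                features,
                known_labels=matrix.sample_conditions[cols],
            )
            reports["splice_feature_classification"] = {
                "n_features": len(features),
                "accuracy": res.accuracy,
            }
            (out / "dendrogram_splice.nwk").write_text(res.newick + "\n")
        indep = pd.read_csv(
            _require(config.independent_matrix, "independent matrix"),
            sep="\t",
            index_col="feature",
        )
        ilabels = pd.read_csv(
            _require(config.independent_labels, "independent labels"),
            sep="\t",
            index_col="sample",
        )["label"]
        ires = splicing.classify_samples(indep, list(indep.index), known_labels=ilabels)
        reports["independent_classification"] = {
            "n_features": int(indep.shape[0]),
            "accuracy": ires.accuracy,
        }
        with open(out / "classification_report.json", "w") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
        bundle["classification"] = reports
        manifest["stages"]["classification"] = reports
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classification", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
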