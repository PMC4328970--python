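"""End-to-end orchestration: data in (or simulated) -> DEGs -> per-condition
networks -> module preservation -> selection analysis, with one config
object, per-stage logging and reproducible text artifacts.

Every numeric threshold defaults to the value used throughout the package:
DEG gates |log2 ratio| > 0.5, p < 0.009, FDR < 0.02; soft-threshold power
beta = 10; dendrogram cut height 0.995 with minimum module size 30;
backbone of the top 300 connections with hub threshold 15; preservation at
>50% overlap with p < 0.001; SNP frequency filter at 5%.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, expression, network, selection, simulate
from .expression import ExpressionDataset
from .simulate import SyntheticExpressionConfig

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs"]

log = logging.getLogger("coexdiv")


@dataclass
class PipelineConfig:
    """All tunables of an end-to-end run, with the standard defaults."""

    # inputs: either paths to data or a synthetic design
    counts_path: str | None = None
    samples_path: str | None = None
    cds_path: str | None = None
    vcf_path: str | None = None
    groups_path: str | None = None  # TSV: individual, group
    synthetic: SyntheticExpressionConfig | None = None

    # DEG thresholds
    deg_log2_ratio: float = 0.5
    deg_p: float = 0.009
    deg_fdr: float = 0.02

    # network
    beta: float = 10.0
    cut_height: float = 0.995
    min_module_size: int = 30

    # comparison
    backbone_k: int = 300
    hub_min_connections: int = 15
    preservation_fraction: float = 0.5
    preservation_p: float = 0.001

    # selection
    snp_min_frequency: float = 0.05
    selection_groups: tuple[str, str] = ("domestic", "wild")
    n_individuals_per_group: int = 24
    cds_codon_length: int = 150

    seed: int = 0
    output_dir: str = "coexdiv_out"
    use_deg_filter: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            for key in ("module_sizes", "conditions", "baseline_log2_range",
                        "module_baseline_log2_range"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = SyntheticExpressionConfig(**syn)
        if d.get("selection_groups") is not None:
            d["selection_groups"] = tuple(d["selection_groups"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"config": self.config,
                                          "stages": self.stages,
                                          "timings": self.timings},
                                         indent=2, sort_keys=True, default=str))


def _log2_tpm(dataset: ExpressionDataset, genes=None) -> pd.DataFrame:
    tpm = dataset.tpm
    if genes is not None:
        tpm = tpm.loc[genes]
    return np.log2(tpm + 1.0)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write all artifacts under ``config.output_dir``.

    With a synthetic config the expression data, coding sequences and SNP
    table are simulated (module genes receive synthetic CDS and variants);
    otherwise they are read from the configured paths.  Identical config
    and seed give identical artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    t_all = time.time()

    # ---- stage 1: data -----------------------------------------------------
    t0 = time.time()
    truth = None
    if config.synthetic is not None:
        datasets, truth = simulate.generate_expression_dataset(config.synthetic)
        for cond, ds in datasets.items():
            ds.to_tsv(out / f"counts_{cond}.tsv", out / f"samples_{cond}.tsv")
            truth.labels[cond].rename("true_module").rename_axis("gene").to_csv(
                out / f"truth_{cond}.tsv", sep="\t"
            )
    elif config.counts_path and config.samples_path:
        full = ExpressionDataset.from_tsv(config.counts_path, config.samples_path)
        conditions = list(dict.fromkeys(full.samples["condition"]))
        if len(conditions) != 2:
            raise ValueError(f"expected 2 conditions, found {conditions}")
        datasets = {c: full.for_condition(c) for c in conditions}
    else:
        raise ValueError("config needs either a synthetic design or counts/samples paths")
    conditions = list(datasets)
    report.stages["data"] = {
        c: {"genes": int(len(ds.genes)), "samples": int(ds.counts.shape[1])}
        for c, ds in datasets.items()
    }
    report.timings["data"] = time.time() - t0
    log.info("data: %s", report.stages["data"])

    # ---- stage 2: DEGs -----------------------------------------------------
    t0 = time.time()
    periods = list(dict.fromkeys(next(iter(datasets.values())).samples["period"]))
    deg_sets: dict[tuple[str, str], list[str]] = {}
    for cond, ds in datasets.items():
        for period in periods:
            if config.use_deg_filter:
                table = expression.detect_temporal_degs(
                    ds,
                    period,
                    log2_ratio_threshold=config.deg_log2_ratio,
                    p_threshold=config.deg_p,
                    fdr_threshold=config.deg_fdr,
                )
                table.to_csv(out / f"degs_{cond}_{period}.tsv", sep="\t", index=False)
                deg_sets[(cond, period)] = expression.deg_gene_set(table)
            else:
                deg_sets[(cond, period)] = list(ds.genes)
    report.stages["degs"] = {
        f"{c}_{p}": len(g) for (c, p), g in deg_sets.items()
    }
    report.timings["degs"] = time.time() - t0
    log.info("degs: %s", report.stages["degs"])

    # ---- stage 3: networks -------------------------------------------------
    t0 = time.time()
    networks: dict[tuple[str, str], network.CoexpressionModules] = {}
    n_modules = {}
    for (cond, period), genes in deg_sets.items():
        key = f"{cond}_{period}"
        if len(genes) == 0:
            log.warning("0 genes pass DEG thresholds for %s; empty network", key)
            n_modules[key] = 0
            continue
        ds = datasets[cond].for_period(period)
        expr = _log2_tpm(ds, genes)
        variable = expr.std(axis=1) > 0
        expr = expr.loc[variable]
        est = network.CoexpressionModules(
            beta=config.beta,
            cut_height=config.cut_height,
            min_module_size=config.min_module_size,
        ).fit(expr)
        networks[(cond, period)] = est
        est.module_set_.to_tsv(out / f"modules_{key}.tsv")
        (out / f"dendrogram_{key}.nwk").write_text(
            network.linkage_to_newick(est.linkage_, est.genes_) + "\n"
        )
        eig = est.eigengenes(expr)
        rows = [
            {"module": m, "sample": s, "v1": float(v)}
            for m, e in eig.items()
            for s, v in e.v1.items()
        ]
        pd.DataFrame(rows, columns=["module", "sample", "v1"]).to_csv(
            out / f"eigengenes_{key}.tsv", sep="\t", index=False
        )
        n_modules[key] = est.module_set_.n_modules
    report.stages["networks"] = n_modules
    report.timings["networks"] = time.time() - t0
    log.info("networks: %s", n_modules)

    # ---- stage 4: module comparison ---------------------------------------
    t0 = time.time()
    comp_stats = {}
    hubs_per_module = {}
    module_class: dict[str, str] = {}  # gene -> "<period> common|specific"
    for period in periods:
        keys = [(c, period) for c in conditions]
        if any(k not in networks for k in keys):
            comp_stats[period] = {"preserved_pairs": 0, "specific_a": 0, "specific_b": 0}
            continue
        na, nb = networks[keys[0]], networks[keys[1]]
        table = comparison.compare_module_sets(
            na.module_set_.assignment,
            nb.module_set_.assignment,
            fraction_threshold=config.preservation_fraction,
            p_threshold=config.preservation_p,
        )
        table.to_csv(out / f"preservation_{period}.tsv", sep="\t", index=False)
        preserved = table[table["preserved"]]
        preserved_a = set(preserved["module_a"])
        preserved_b = set(preserved["module_b"])
        spec_a = [m for m in na.module_set_.modules if m not in preserved_a]
        spec_b = [m for m in nb.module_set_.modules if m not in preserved_b]
        comp_stats[period] = {
            "preserved_pairs": int(len(preserved)),
            "specific_a": len(spec_a),
            "specific_b": len(spec_b),
        }
        # gene -> module class for the selection stage
        for est, spec in ((na, spec_a), (nb, spec_b)):
            for m in est.module_set_.modules:
                cls = "common" if m not in spec else "specific"
                for g in est.module_set_.genes_in(m):
                    module_class.setdefault(g, f"{period} {cls}")
        # backbones and hubs
        hub_rows = []
        for est, side in ((na, keys[0][0]), (nb, keys[1][0])):
            for m in est.module_set_.modules:
                backbone = comparison.module_backbone(
                    est.tom_ if isinstance(est.tom_, pd.DataFrame)
                    else pd.DataFrame(est.tom_, index=est.genes_, columns=est.genes_),
                    est.module_set_.genes_in(m),
                    k=config.backbone_k,
                )
                backbone.to_csv(
                    out / f"backbone_{side}_{period}_{m}.tsv", sep="\t", index=False
                )
                hubs = comparison.hub_genes(backbone, config.hub_min_connections)
                hubs_per_module[f"{side}_{period}_{m}"] = int(len(hubs))
                for _, row in hubs.iterrows():
                    hub_rows.append(
                        {"network": side, "period": period, "module": m,
                         "gene": row["gene"], "degree": int(row["degree"])}
                    )
        pd.DataFrame(
            hub_rows, columns=["network", "period", "module", "gene", "degree"]
        ).to_csv(out / f"hubs_{period}.tsv", sep="\t", index=False)
    report.stages["comparison"] = comp_stats
    report.stages["hubs"] = hubs_per_module
    report.timings["comparison"] = time.time() - t0
    log.info("comparison: %s", comp_stats)

    # ---- stage 5: selection ------------------------------------------------
    t0 = time.time()
    module_genes = sorted(module_class)
    ga, gb = config.selection_groups
    if config.synthetic is not None and module_genes:
        # synthesize CDS + SNPs for the module genes
        rng = np.random.default_rng(config.seed + 1)
        references = {}
        for g in module_genes:
            ref, _, _, _ = simulate.generate_coding_alignment(
                config.cds_codon_length, 0, 0, seed=int(rng.integers(2**31))
            )
            references[g] = ref
        records, _ = simulate.generate_snp_table(
            references,
            config.n_individuals_per_group,
            seed=int(rng.integers(2**31)),
            groups=config.selection_groups,
        )
        with open(out / "cds.fasta", "w") as fh:
            for g, seq in references.items():
                fh.write(f">{g}\n{seq}\n")
        group_of = {
            f"{grp}{i + 1:02d}": grp
            for grp in config.selection_groups
            for i in range(config.n_individuals_per_group)
        }
        selection.write_snp_vcf(
            records, out / "snps.vcf", group_of,
            {g: len(s) for g, s in references.items()},
        )
    elif config.cds_path and config.vcf_path and config.groups_path:
        from Bio import SeqIO

        references = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(config.cds_path, "fasta")
        }
        groups_tbl = pd.read_csv(config.groups_path, sep="\t")
        group_of = dict(zip(groups_tbl["individual"], groups_tbl["group"]))
        records = selection.read_snp_vcf(config.vcf_path, group_of)
    else:
        references, records = {}, []

    results = []
    if references:
        kept = selection.filter_snps(records, config.snp_min_frequency)
        by_gene: dict[str, list] = {}
        for r in kept:
            by_gene.setdefault(r.gene, []).append(r)
        observed_any = {r.gene for r in records}
        for g in sorted(references):
            recs = by_gene.get(g, [])
            cons_a = selection.consensus_sequence(references[g], recs, ga)
            cons_b = selection.consensus_sequence(references[g], recs, gb)
            results.append(
                selection.ng86_ka_ks(cons_a, cons_b, gene=g,
                                     snps_observed=g in observed_any)
            )
        pd.DataFrame(
            {
                "gene": [r.gene for r in results],
                "ka": [r.ka for r in results],
                "ks": [r.ks for r in results],
                "ratio_or_sentinel": [
                    "" if r.ratio is None else r.ratio for r in results
                ],
                "category": [r.category for r in results],
            }
        ).to_csv(out / "selection.tsv", sep="\t", index=False)
        histogram = selection.bin_ka_ks([r for r in results if not r.flagged])
        histogram.to_csv(out / "selection_histogram.tsv", sep="\t", index=False)
        positive = selection.positively_selected_genes(results, module_class)
        positive.to_csv(out / "positively_selected.tsv", sep="\t", index=False)
        report.stages["selection"] = {
            "genes": len(results),
            "snps_total": len(records),
            "snps_kept": len(kept),
            "categories": dict(zip(histogram["category"], map(int, histogram["count"]))),
            "positively_selected": int(len(positive)),
        }
    else:
        report.stages["selection"] = {"genes": 0}
    report.timings["selection"] = time.time() - t0
    log.info("selection: %s", report.stages["selection"])

    report.timings["total"] = time.time() - t_all
    report.to_json(out / "report.json")
    config.to_yaml(out / "config.yaml")
    return report


def validate_inputs(
    counts_path: str | None = None,
    samples_path: str | None = None,
    cds_path: str | None = None,
    vcf_path: str | None = None,
) -> list[dict]:
    """Check input files for format problems without running the pipeline.

    Returns a list of diagnostics ``{"file", "level", "message"}`` with
    level ``"fatal"`` or ``"warning"``.
    """
    diags: list[dict] = []

    def add(file, level, message):
        diags.append({"file": str(file), "level": level, "message": message})

    counts = None
    if counts_path:
        try:
            counts = pd.read_csv(counts_path, sep="\t", index_col=0)
            if counts.empty:
                add(counts_path, "fatal", "empty counts matrix")
            elif (counts.to_numpy() < 0).any():
                add(counts_path, "fatal", "negative counts")
            else:
                add(counts_path, "ok",
                    f"{counts.shape[0]} genes x {counts.shape[1]} samples")
        except Exception as exc:  # unreadable counts are fatal
            add(counts_path, "fatal", f"unreadable: {exc}")
    if samples_path:
        try:
            samples = pd.read_csv(samples_path, sep="\t", index_col=0)
            for col in expression.REQUIRED_SAMPLE_COLUMNS:
                if col not in samples.columns:
                    add(samples_path, "fatal", f"missing column {col!r}")
            if counts is not None:
                missing = set(map(str, counts.columns)) - set(map(str, samples.index))
                if missing:
                    add(samples_path, "fatal",
                        f"samples in counts matrix missing from metadata: {sorted(missing)}")
        except Exception as exc:
            add(samples_path, "fatal", f"unreadable: {exc}")
    lengths = {}
    if cds_path:
        try:
            from Bio import SeqIO

            for rec in SeqIO.parse(str(cds_path), "fasta"):
                lengths[rec.id] = len(rec.seq)
                if len(rec.seq) % 3:
                    add(cds_path, "fatal",
                        f"sequence {rec.id} length {len(rec.seq)} not a multiple of 3")
            if not lengths:
                add(cds_path, "fatal", "no FASTA records")
        except Exception as exc:
            add(cds_path, "fatal", f"unreadable: {exc}")
    if vcf_path:
        try:
            import pysam

            with pysam.VariantFile(str(vcf_path)) as vcf:
                for rec in vcf:
                    if lengths and rec.chrom in lengths and rec.pos > lengths[rec.chrom]:
                        add(vcf_path, "fatal",
                            f"record {rec.chrom}:{rec.pos} beyond CDS length "
                            f"{lengths[rec.chrom]}")
        except Exception as exc:
            add(vcf_path, "fatal", f"unreadable: {exc}")
    return diags
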