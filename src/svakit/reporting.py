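"""Cohort statistics, targeted-sequencing statistics and pipeline orchestration.

``cohort_summary`` gives the mean and sample (n-1) standard deviation of a
numeric cohort field, excluding (and counting) records missing it.
``on_target_stats`` summarizes Cas9-targeted sequencing yield: per-sample
on-target proportions and their unweighted mean (the pooled alternative —
summed on-target over summed totals — is also reported, never silently
reconciled with a user-supplied grand total).  ``run_pipeline`` chains the
whole toolkit over a synthetic fixture or pre-existing inputs and writes a
per-stage report directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment, catalog, expression, methylation, profiles, repeats, synthetic
from .io import read_bed, read_bedgraph, read_fasta, read_gtf, write_fasta, write_gtf

logger = logging.getLogger(__name__)


@dataclass
class CohortRecord:
    participant_id: str
    status: str  # case / control
    age_at_onset: float | None = None
    age_at_collection: float | None = None
    hexamer_copies: int | None = None

    def __post_init__(self):
        for age in (self.age_at_onset, self.age_at_collection):
            if age is not None and age <= 0:
                raise ValueError("ages must be > 0 when present")


@dataclass
class CohortSummary:
    field: str
    n: int
    mean: float
    sd: float | None  # None when n == 1
    n_missing: int


def cohort_summary(records: list[CohortRecord], field: str) -> CohortSummary:
    """Mean and sample s.d. of one cohort field (missing values excluded)."""
    values = [getattr(r, field) for r in records]
    present = [v for v in values if v is not None]
    if not present:
        raise ValueError(f"no record carries a value for {field!r}")
    arr = np.asarray(present, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return CohortSummary(field=field, n=len(arr), mean=float(arr.mean()), sd=sd,
                         n_missing=len(values) - len(arr))


@dataclass
class OnTargetStats:
    samples: list[tuple[int, int, float]]  # (total, on_target, proportion)
    mean_proportion: float  # unweighted mean of per-sample proportions
    pooled_proportion: float  # sum(on_target) / sum(total)


def on_target_stats(per_sample: list[tuple[int, int]]) -> OnTargetStats:
    """On-target read statistics for targeted sequencing runs.

    ``per_sample`` holds (total reads, on-target primary reads) pairs.  The
    headline figure is the unweighted mean of the per-sample proportions.
    """
    if not per_sample:
        raise ValueError("need at least one sample")
    samples = []
    for total, on_target in per_sample:
        if total <= 0:
            raise ValueError("total read count must be > 0")
        if not 0 <= on_target <= total:
            raise ValueError(f"on-target count {on_target} exceeds total {total}")
        samples.append((total, on_target, on_target / total))
    mean_prop = float(np.mean([p for _, _, p in samples]))
    pooled = sum(o for _, o, _ in samples) / sum(t for t, _, _ in samples)
    return OnTargetStats(samples=samples, mean_proportion=mean_prop, pooled_proportion=pooled)


# ---------------------------------------------------------------------------
# pipeline orchestration

_INPUT_KEYS = ("genome", "elements", "annotation", "insertions", "signal", "alignments",
               "spikein", "methylation", "counts", "samples",
               "readthrough_plus", "readthrough_minus")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config) -> dict:
    """Run every stage over a synthetic fixture (or named input files).

    The config (dict or YAML path) takes an ``outdir``, a ``seed``, optional
    ``simulate`` overrides for :class:`synthetic.SimConfig`, optional
    ``thresholds`` overrides for insertion filtering, or — instead of
    simulation — an ``inputs`` mapping naming pre-existing files.  Identical
    config+seed reproduces identical outputs.  Returns the summary dict
    (also written as ``summary.json``).
    """
    cfg = load_config(config)
    outdir = Path(cfg.get("outdir", "svakit_report"))
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("svakit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"stages": []}

    try:
        # stage 0: inputs
        truth = None
        if "inputs" in cfg:
            paths = {k: str(v) for k, v in cfg["inputs"].items()}
            missing = [k for k in _INPUT_KEYS if k not in paths or not Path(paths[k]).exists()]
            if missing:
                raise PipelineError("inputs", f"missing input files: {missing}")
        else:
            sim_kwargs = dict(cfg.get("simulate", {}))
            if "element_length_range" in sim_kwargs:
                sim_kwargs["element_length_range"] = tuple(sim_kwargs["element_length_range"])
            if "hexamer_copies_range" in sim_kwargs:
                sim_kwargs["hexamer_copies_range"] = tuple(sim_kwargs["hexamer_copies_range"])
            sim_kwargs.setdefault("seed", int(cfg.get("seed", 0)))
            sim_config = synthetic.SimConfig(**sim_kwargs)
            paths, truth = synthetic.write_fixture(sim_config, outdir / "fixture")
        summary["stages"].append("inputs")
        logger.info("inputs ready: %d files", len(paths))

        # stage 1: insertion catalog
        stage = "catalog"
        calls = catalog.read_insertion_table(paths["insertions"])
        thresholds = catalog.FilterThresholds(**cfg.get("thresholds", {}))
        kept = catalog.filter_insertions(calls, thresholds)
        catalog.write_insertion_table(kept, outdir / "insertions.filtered.tsv")
        catalog.write_calls_bed(kept, outdir / "insertions.filtered.bed")
        by_sample: dict[str, list] = {}
        for call in kept:
            for sample in call.sample_ids or {"unknown"}:
                by_sample.setdefault(sample, []).append(call)
        partition = catalog.shared_and_private(by_sample)
        summary["catalog"] = {
            "n_calls": len(calls),
            "n_pass_filter": len(kept),
            "n_shared_events": partition.n_shared,
            "n_private_events": partition.n_private,
        }
        summary["stages"].append(stage)
        logger.info("catalog: %d/%d calls pass filters", len(kept), len(calls))

        # stage 2: genome augmentation + liftover
        stage = "augment"
        genome = read_fasta(paths["genome"])
        plan = [
            augment.Insertion(c.chromosome, c.start, c.consensus, f"{c.subfamily}@{c.start}")
            for c in kept
        ]
        augmented, cmap = augment.augment_genome(genome, plan)
        write_fasta(augmented, outdir / "augmented.fa")
        cmap.to_tsv(outdir / "coordinate_map.tsv")
        annotation = read_gtf(paths["annotation"])
        lifted = augment.lift_annotation(annotation, cmap)
        write_gtf(lifted, outdir / "annotation.lifted.gtf")
        summary["augment"] = {
            "bases_inserted": sum(len(i.sequence) for i in plan),
            "length_conserved": all(
                len(augmented[c]) - len(genome[c])
                == sum(len(i.sequence) for i in plan if i.chromosome == c)
                for c in genome
            ),
        }
        summary["stages"].append(stage)

        # stage 3: coverage profiling
        stage = "profiles"
        elements = read_bed(paths["elements"])
        track = profiles.CoverageTrack.from_bedgraph_dict(read_bedgraph(paths["signal"]))
        spikein = int(Path(paths["spikein"]).read_text().strip())
        stats = profiles.spikein_scale_factor(spikein)
        scaled = track.scale(stats.scale_factor)
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        matrix = profiles.scale_regions_matrix(scaled, elements, chrom_sizes=chrom_sizes)
        matrix.to_tsv(outdir / "profile_matrix.tsv")
        ratios = profiles.boundary_enrichment(matrix, window=1000)
        pd.DataFrame(
            {"element_id": list(ratios), "boundary_ratio": list(ratios.values())}
        ).to_csv(outdir / "boundary_enrichment.tsv", sep="\t", index=False)
        alignments = profiles.read_sam(paths["alignments"])
        kept_alignments = profiles.filter_alignments(alignments)
        summary["profiles"] = {
            "spikein_scale_factor": stats.scale_factor,
            "n_alignments": len(alignments),
            "n_alignments_pass": len(kept_alignments),
            "enriched_elements": sorted(
                eid for eid, r in ratios.items() if np.isfinite(r) and r >= 2.0
            ),
        }
        summary["stages"].append(stage)

        # stage 4: methylation
        stage = "methylation"
        calls_df = methylation.read_call_table(paths["methylation"])
        binarized = methylation.binarize_calls(calls_df)
        per_condition: dict[str, list] = {}
        for condition, sub in binarized.calls.groupby("condition"):
            summaries = methylation.elements_methylation(sub, elements)
            per_condition[condition] = summaries
            methylation.summaries_to_frame(summaries).to_csv(
                outdir / f"methylation.{condition}.tsv", sep="\t", index=False
            )
        demethylated = []
        if {"control", "knockdown"} <= per_condition.keys():
            control = {s.element_id: s for s in per_condition["control"]}
            for s in per_condition["knockdown"]:
                c = control.get(s.element_id)
                if c and np.isfinite(c.mean_methylation) and np.isfinite(s.mean_methylation) \
                        and c.mean_methylation - s.mean_methylation > 0.3:
                    demethylated.append(s.element_id)
            comparison = methylation.compare_methylation(
                per_condition["control"], per_condition["knockdown"], region="full"
            )
            summary["methylation"] = {
                "demethylated_elements": sorted(demethylated),
                "mean_control": comparison.mean_a,
                "mean_knockdown": comparison.mean_b,
                "p_value": comparison.p_value,
            }
        summary["stages"].append(stage)

        # stage 5: hexamer repeats
        stage = "repeats"
        hexamer = {}
        for el in elements:
            seq = genome[el.chrom][el.start:el.end]
            report = repeats.hexamer_report([seq])
            hexamer[el.name] = report.copies
        pd.DataFrame(
            {"element_id": list(hexamer), "hexamer_copies": list(hexamer.values())}
        ).to_csv(outdir / "hexamer_copies.tsv", sep="\t", index=False)
        summary["repeats"] = {"hexamer_copies": hexamer}
        summary["stages"].append(stage)

        # stage 6: expression
        stage = "expression"
        table = expression.CountTable.from_tsv(paths["counts"], paths["samples"])
        tpms = expression.tpm(table)
        tpms.to_csv(outdir / "tpm.tsv", sep="\t")
        factors = expression.size_factors_median_ratios(table)
        factors.to_csv(outdir / "size_factors.tsv", sep="\t")
        links = expression.link_elements_to_genes(elements, annotation)
        pd.DataFrame([l.__dict__ for l in links]).to_csv(
            outdir / "gene_links.tsv", sep="\t", index=False
        )
        summary["expression"] = {"n_gene_links": len(links)}
        if truth is not None and truth.target_intron_id:
            retention = expression.intron_retention(
                table, truth.target_intron_id, truth.target_exon_id,
                ("control", "double_kd"),
            )
            summary["expression"]["intron_ratio"] = retention.intron_ratio
            summary["expression"]["exon_ratio"] = retention.exon_ratio
            summary["expression"]["intron_up"] = retention.intron_up
        plus = profiles.CoverageTrack.from_bedgraph_dict(
            read_bedgraph(paths["readthrough_plus"])
        )
        minus = profiles.CoverageTrack.from_bedgraph_dict(
            read_bedgraph(paths["readthrough_minus"])
        )
        readthrough = [
            expression.detect_readthrough(plus, minus, el, annotation) for el in elements
        ]
        calls_with_extent = [r for r in readthrough if r.extent > 0]
        pd.DataFrame([r.__dict__ for r in readthrough]).to_csv(
            outdir / "readthrough.tsv", sep="\t", index=False
        )
        summary["expression"]["readthrough_elements"] = sorted(
            r.element_id for r in calls_with_extent
        )
        summary["stages"].append(stage)

        # truth-set recovery (only when simulating)
        if truth is not None:
            summary["recovery"] = {
                "planted_insertions": len(truth.insertions),
                "recovered_insertions": summary["catalog"]["n_pass_filter"],
                "planted_enriched": sorted(truth.enriched_element_ids),
                "planted_demethylated": sorted(truth.demethylated_element_ids),
                "planted_readthrough": truth.readthrough_element_id,
            }

        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
        _write_report_md(outdir, summary)
        return summary
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(stage if "stage" in dir() else "inputs", str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_report_md(outdir: Path, summary: dict) -> None:
    lines = ["# svakit pipeline report", ""]
    for stage in summary["stages"]:
        lines.append(f"## {stage}")
        for key, value in summary.get(stage, {}).items():
            lines.append(f"- {key}: {value}")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
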