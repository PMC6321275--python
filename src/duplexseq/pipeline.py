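"""Orchestration of the full analysis over one dataset and across treatments.

A dataset is one sequencing library (one treatment of one sample).
``run_dataset`` executes the stage chain trim -> length filter -> map ->
coverage -> all-vs-all scan (plus shuffled control) -> chimera search ->
antisense contingency, writing stage TSVs, a summary JSON and a run log
into the manifest's output directory.  ``compare_treatments`` joins
several summaries into the treatment-contrast table (helix-length medians,
per-class enrichment ratios over a baseline, antisense factors, chimera
counts).  Every number in the comparison is recomputable from the stage
TSVs; reruns with the same manifest are byte-identical because all
stochastic stages are re-seeded from the manifest seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import antisense as anti
from . import chimera as chim
from . import mapping, scan, seqio
from .energy import DEFAULT_MODEL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisParams:
    """Stage parameters; defaults follow the protocol's analysis settings."""

    trim_window: int = 10
    trim_qmin: int = 20
    min_read_length_exclusive: int = 18
    scan_engine: str = "energy"
    scan_dedup: bool = True
    shuffle_mode: str = "mono"
    chimera_min_match: int = 18
    zscore_cutoff: float = -3.0


@dataclass(frozen=True)
class RunManifest:
    """Bookkeeping for one dataset run."""

    dataset_label: str
    treatment: str
    fastq: str
    transcripts_fasta: str
    transcripts_tsv: str
    outdir: str
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self.params), sort_keys=True
        ) + self.treatment
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


STAGES = (
    "trim",
    "length_filter",
    "map",
    "coverage",
    "scan",
    "scan_shuffled",
    "chimera",
    "antisense",
)


def run_dataset(manifest: RunManifest) -> dict:
    """Execute all stages for one dataset; returns the summary report.

    Outputs written under ``manifest.outdir``: matches.tsv, coverage.tsv,
    class_coverage.tsv, scan.tsv, scan_hist.tsv, chimera.tsv,
    contingency.json, summary.json, run.log.  A stage failure raises with
    the stage name; earlier outputs are left in place.
    """
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = manifest.params
    log_lines: list[str] = []

    def stage_log(stage: str, n_in: int, n_out: int) -> None:
        line = f"{manifest.dataset_label}\t{stage}\tin={n_in}\tout={n_out}"
        logger.info(line)
        log_lines.append(line)

    current = "load"
    try:
        reads = seqio.read_fastq(manifest.fastq)
        transcripts = seqio.read_transcripts(
            manifest.transcripts_fasta, manifest.transcripts_tsv
        )
        stage_log("load", len(reads), len(reads))

        current = "trim"
        trimmed = [
            t
            for t in (
                seqio.quality_trim(r, p.trim_window, p.trim_qmin) for r in reads
            )
            if t is not None
        ]
        stage_log("trim", len(reads), len(trimmed))

        current = "length_filter"
        kept = seqio.length_filter(trimmed, p.min_read_length_exclusive)
        stage_log("length_filter", len(trimmed), len(kept))

        current = "map"
        index = mapping.TranscriptIndex(transcripts)
        matches = mapping.map_reads(kept, index)
        pd.DataFrame(
            [dataclasses.asdict(m) for m in matches]
        ).to_csv(outdir / "matches.tsv", sep="\t", index=False)
        stage_log("map", len(kept), len(matches))

        current = "coverage"
        profiles = mapping.coverage_profiles(matches, transcripts)
        cov_rows = []
        for tid, prof in profiles.items():
            norm = mapping.normalize_profile(prof)
            for pos, (v, nv) in enumerate(zip(prof.cov, norm.cov)):
                if v > 0:
                    cov_rows.append(
                        {"transcript_id": tid, "pos": pos, "cov": v, "cov_norm": nv}
                    )
        pd.DataFrame(cov_rows).to_csv(outdir / "coverage.tsv", sep="\t", index=False)
        class_cov = mapping.gene_class_coverage(profiles, transcripts)
        pd.Series(class_cov, name="mean_coverage").rename_axis("gene_class").to_csv(
            outdir / "class_coverage.tsv", sep="\t"
        )
        stage_log("coverage", len(matches), len(class_cov))

        current = "scan"
        profile = scan.all_vs_all_scan(
            kept, p.scan_engine, p.scan_dedup, DEFAULT_MODEL, manifest.dataset_label
        )
        median, maximum, hist = (
            scan.scan_summary(profile) if profile.per_read_max else (0.0, 0, {})
        )
        pd.DataFrame(
            [
                {
                    "read_id": rid,
                    "length": length,
                    "max_helix_bp": profile.per_read_max[rid],
                    "best_partner_id": profile.best_partner[rid] or "",
                }
                for rid, length in ((r.read_id, len(r)) for r in kept)
            ]
        ).to_csv(outdir / "scan.tsv", sep="\t", index=False)
        stage_log("scan", len(kept), profile.n_pairs_scored)

        current = "scan_shuffled"
        shuffled = scan.shuffled_control_scan(
            kept,
            p.scan_engine,
            manifest.seed,
            p.shuffle_mode,
            p.scan_dedup,
            DEFAULT_MODEL,
            manifest.dataset_label,
        )
        s_median, s_max, s_hist = (
            scan.scan_summary(shuffled) if shuffled.per_read_max else (0.0, 0, {})
        )
        hist_rows = [
            {"helix_bp": k, "count": v, "shuffled": False} for k, v in sorted(hist.items())
        ] + [
            {"helix_bp": k, "count": v, "shuffled": True}
            for k, v in sorted(s_hist.items())
        ]
        pd.DataFrame(hist_rows).to_csv(outdir / "scan_hist.tsv", sep="\t", index=False)
        stage_log("scan_shuffled", len(kept), shuffled.n_pairs_scored)

        current = "chimera"
        calls = chim.find_chimeras(kept, index, p.chimera_min_match)
        pd.DataFrame(
            [
                {
                    "read_id": c.read_id,
                    "tx5": c.five_prime[0],
                    "span5": f"{c.five_prime[1]}-{c.five_prime[2]}",
                    "tx3": c.three_prime[0],
                    "span3": f"{c.three_prime[1]}-{c.three_prime[2]}",
                    "gap": c.gap,
                    "ambiguous": c.ambiguous,
                }
                for c in calls
            ]
        ).to_csv(outdir / "chimera.tsv", sep="\t", index=False)
        stage_log("chimera", len(kept), len(calls))

        current = "antisense"
        overlap_flags = anti.annotate_antisense_overlap(transcripts)
        match_flags = anti.gene_match_flags(matches, transcripts)
        table = anti.build_contingency(
            overlap_flags, match_flags, manifest.dataset_label
        )
        try:
            factor = anti.enrichment_factor(table)
        except ValueError:
            factor = float("nan")
        (outdir / "contingency.json").write_text(
            json.dumps(
                {
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "enrichment_factor": factor,
                },
                indent=1,
            )
        )
        stage_log("antisense", table.n_genes, 1)
    except Exception as exc:
        raise RuntimeError(
            f"stage {current!r} failed for dataset {manifest.dataset_label}: {exc}"
        ) from exc

    summary = {
        "dataset_label": manifest.dataset_label,
        "treatment": manifest.treatment,
        "seed": manifest.seed,
        "config_hash": manifest.config_hash,
        "stages": list(STAGES),
        "n_reads_raw": len(reads),
        "n_reads_trimmed": len(trimmed),
        "n_reads_kept": len(kept),
        "n_matches": len(matches),
        "class_coverage": class_cov,
        "scan_median": median,
        "scan_max": maximum,
        "scan_median_shuffled": s_median,
        "scan_max_shuffled": s_max,
        "n_chimera_calls": len(calls),
        "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "antisense_factor": factor,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def compare_treatments(reports: list[dict]) -> dict:
    """Join per-dataset summaries into one treatment comparison.

    Class-coverage ratios are computed against the baseline report (the
    first one labeled 'native', else the first report).  Requires at least
    two reports; differing config hashes are flagged, not fatal.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    hashes = {r["config_hash"] for r in reports}
    baseline = next(
        (r for r in reports if r["treatment"] == "native"), reports[0]
    )
    comparison = {
        "baseline": baseline["dataset_label"],
        "config_mismatch": len(hashes) > 1,
        "datasets": {},
    }
    for r in reports:
        ratios = mapping.class_enrichment(
            r["class_coverage"], baseline["class_coverage"]
        )
        comparison["datasets"][r["dataset_label"]] = {
            "treatment": r["treatment"],
            "scan_median": r["scan_median"],
            "scan_median_shuffled": r["scan_median_shuffled"],
            "scan_max": r["scan_max"],
            "class_enrichment_vs_baseline": ratios,
            "antisense_factor": r["antisense_factor"],
            "n_chimera_calls": r["n_chimera_calls"],
        }
    return comparison
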