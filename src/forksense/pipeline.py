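"""End-to-end orchestration: simulate -> enrich -> compare -> signal -> ipms.

``run_all`` executes every stage on a synthetic study (or user-supplied
inputs loaded through :mod:`forksense.io`), writes one TSV per stage plus
a JSON manifest recording the configuration snapshot, seed, input digests
and output paths.  A single seed drives deterministic per-stage
substreams, so rerunning with the same manifest inputs reproduces the
deterministic outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .dynamics import compare_conditions, venn_counts
from .enrichment import enrichment_analysis
from .intervals import FeatureSet
from .io import write_fasta, write_peak_table, write_results
from .proteomics import interaction_table
from .simulate import SimulationSpec, simulate_coverage, simulate_study
from .tracks import extract_region, hanning_smooth, log2_ratio

__all__ = ["RunManifest", "run_all", "enrichment_to_frame", "comparison_to_frame"]


@dataclass
class RunManifest:
    seed: int
    config: dict
    simulation: dict
    outputs: dict[str, str] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def enrichment_to_frame(results) -> pd.DataFrame:
    """Association results as a table mirroring the feature / n / fraction / p layout."""
    return pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "n_features": [r.n_features for r in results],
            "n_associated": [r.n_associated for r in results],
            "fraction": [r.fraction for r in results],
            "p_value": [str(r.pvalue) for r in results],
            "significant": [r.significant for r in results],
        }
    )


def comparison_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "n_regions": [r.n_regions for r in results],
            "fraction_stronger_depleted": [r.fraction_stronger_b for r in results],
            "wilcoxon_p": [str(r.wilcoxon) if r.wilcoxon else "NA" for r in results],
        }
    )


def run_all(
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    sim_spec: SimulationSpec | None = None,
    seed: int | None = None,
    make_plots: bool = False,
) -> RunManifest:
    """Run the full synthetic pipeline and write result tables + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = AnalysisConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    if sim_spec is None:
        sim_spec = SimulationSpec(seed=config.seed)
    else:
        sim_spec = replace(sim_spec, seed=config.seed)

    streams = np.random.SeedSequence(config.seed).spawn(3)
    manifest = RunManifest(
        seed=config.seed, config=config.to_dict(), simulation=asdict(sim_spec)
    )

    # --- simulate ---------------------------------------------------------
    study = simulate_study(sim_spec)
    write_fasta(out / "genome.fasta", study.genome)
    manifest.outputs["genome"] = "genome.fasta"
    for cond, table in study.peaks.items():
        path = out / f"peaks_{cond}.tsv"
        write_peak_table(path, table)
        manifest.outputs[f"peaks_{cond}"] = path.name

    # --- enrich: helicase peaks vs every feature class (300 bp window) ----
    enr = enrichment_analysis(
        study.peaks["pfh1_wt"].intervals,
        study.features,
        study.genome,
        config,
        rng=np.random.default_rng(streams[0]),
    )
    write_results(out / "enrichment.tsv", enrichment_to_frame(enr))
    manifest.outputs["enrichment"] = "enrichment.tsv"

    # --- compare: WT vs depleted dynamics + Venn overlaps -----------------
    strata = [fs for fs in study.features if fs.name in ("trna_like", "ndr")]
    rows = []
    for mark in ("cdc20", "gh2a"):
        res = compare_conditions(
            study.peaks[f"{mark}_wt"],
            study.peaks[f"{mark}_depleted"],
            strata,
            window_bp=config.peak_window_bp,
        )
        frame = comparison_to_frame(res)
        frame.insert(0, "mark", mark)
        rows.append(frame)
        vc = venn_counts(study.peaks[f"{mark}_wt"], study.peaks[f"{mark}_depleted"])
        manifest.digests[f"venn_{mark}"] = json.dumps(vc._asdict())
    write_results(out / "comparison.tsv", pd.concat(rows, ignore_index=True))
    manifest.outputs["comparison"] = "comparison.tsv"

    # --- signal: smoothed log2(IP/input) around one enriched feature ------
    rng_cov = np.random.default_rng(streams[1])
    ip, inp = simulate_coverage(
        study.genome,
        study.peaks["pfh1_wt"].intervals,
        depth=sim_spec.coverage_depth,
        fold=sim_spec.coverage_fold,
        rng=rng_cov,
    )
    focus = study.peaks["pfh1_wt"].intervals[0]
    center = (focus.start + focus.end) // 2
    half = 5000
    chrom_len = study.genome.lengths[focus.chrom]
    center = int(np.clip(center, half, chrom_len - half))
    raw = log2_ratio(
        extract_region(ip, focus.chrom, center, half).values,
        extract_region(inp, focus.chrom, center, half).values,
        pseudocount=config.pseudocount,
        chrom=focus.chrom,
        start=center - half,
    )
    smooth = hanning_smooth(raw, config.hanning_bp)
    write_results(
        out / "signal.tsv",
        pd.DataFrame(
            {"chrom": focus.chrom, "pos": smooth.positions, "log2_ratio": smooth.values}
        ),
    )
    manifest.outputs["signal"] = "signal.tsv"
    if make_plots:
        from .tracks import plot_tracks

        plot_tracks(
            {"helicase IP": smooth},
            str(out / "signal.png"),
            gene=(focus.start, focus.end),
        )
        manifest.outputs["signal_plot"] = "signal.png"

    # --- ipms: SAINT filter, NSAF/PAX, phase classes ----------------------
    table, _edges = interaction_table(
        study.records_s,
        saint_threshold=config.saint_threshold,
        records_g2=study.records_g2,
    )
    write_results(out / "ipms.tsv", table)
    manifest.outputs["ipms"] = "ipms.tsv"

    for key, name in list(manifest.outputs.items()):
        p = out / name
        if p.suffix == ".tsv":
            manifest.digests[name] = _sha256(p)
    manifest.write(out / "manifest.json")
    return manifest
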