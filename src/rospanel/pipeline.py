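"""End-to-end pipeline: dose-response -> ranking -> screen -> overlaps.

Given the three input files (or a simulation request), the pipeline
estimates IC25 per (cell line, treatment), builds sensitivity profiles
and cross-treatment statistics, prepares the expression matrix
(replicate averaging, housekeeping normalization, annotation filter),
runs the per-treatment correlation screen, and compares the resulting
top-k gene lists. Every stage's output is written under the output
directory together with a manifest that records the resolved
configuration, seed and per-stage row counts, so a run is exactly
reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd

from importlib.metadata import version as _pkg_version

from rospanel import io
from rospanel.dose_response import baseline_metabolism, fit_ic25, normalize_viability
from rospanel.errors import ValidationError
from rospanel.expression import (
    ExpressionMatrix,
    average_replicates,
    filter_annotated,
    housekeeping_normalize,
)
from rospanel.overlap import GeneSet, overlap_report
from rospanel.screen import ScreenResult, correlate_metabolism, screen, select_top
from rospanel.sensitivity import (
    SensitivityProfile,
    cross_treatment_correlation,
    make_profile,
    rank_ratio,
    rank_sum,
)
from rospanel.synthetic import SimulationConfig, simulate_panel, write_panel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; file paths or a simulation, never both."""

    dose_response_path: str | None = None
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    simulation: SimulationConfig | None = None
    alpha: float = 0.05
    k_signed: int = 20
    k_overall: int = 500
    p_method: str = "t_approx"
    model_variant: str = "two_param"
    hk_gene: str = "RPL13A"
    seed: int = 0
    outdir: str = "rospanel_out"

    def validate(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.k_signed <= 0 or self.k_overall <= 0:
            raise ValidationError("k_signed and k_overall must be positive")
        file_inputs = [self.dose_response_path, self.expression_path,
                       self.sample_sheet_path, self.annotation_path]
        if self.simulation is None:
            missing = [p for p in file_inputs if p is None]
            if missing:
                raise ValidationError(
                    "either all four input paths or a simulation config is required"
                )
            for p in file_inputs:
                if not Path(p).exists():
                    raise ValidationError(f"input file not found: {p}")
        elif any(p is not None for p in file_inputs):
            raise ValidationError("give input paths or a simulation config, not both")


@dataclass
class RunResult:
    """In-memory handles to everything a pipeline run produced."""

    outdir: Path
    ic25: pd.DataFrame
    profiles: dict[str, SensitivityProfile]
    cross_treatment: dict
    matrix: ExpressionMatrix
    screens: dict[str, ScreenResult]
    top_lists: dict[str, dict[str, list[str]]]
    overlaps: dict[str, dict]
    manifest: dict


def _stage(name: str):
    """Wrap stage errors with the failing stage's name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise type(exc)(f"stage '{name}': {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage and write all outputs under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    counts: dict[str, int] = {}

    with _stage("inputs"):
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = replace(sim, seed=config.seed)
            panel = simulate_panel(sim)
            write_panel(panel, outdir / "inputs")
            records = panel.dose_response
            samples = panel.expression_samples
            sheet = panel.sample_sheet
            annotation = panel.annotation
        else:
            records = io.read_dose_response(config.dose_response_path)
            samples = io.read_expression(config.expression_path)
            sheet = io.read_sample_sheet(config.sample_sheet_path)
            annotation = io.read_annotation(config.annotation_path)
        counts["dose_response_rows"] = len(records)
        counts["expression_genes"] = len(samples)
        counts["expression_samples"] = samples.shape[1]

    with _stage("dose_response"):
        curves = normalize_viability(records)
        estimates = [fit_ic25(c, config.model_variant) for c in curves.values()]
        n_failed = sum(not e.converged for e in estimates)
        if n_failed:
            warnings.append(f"dose_response: {n_failed} fits did not converge")
        units = records.groupby("treatment")["unit"].first().to_dict() if "unit" in records else {}
        ic25 = io.ic25_table(estimates, units)
        io.write_tsv(ic25, outdir / "ic25_table.tsv")
        baseline = baseline_metabolism(records)
        io.write_tsv(baseline.reset_index(), outdir / "baseline_metabolism.tsv")
        counts["ic25_estimates"] = len(ic25)

    with _stage("sensitivity_analysis"):
        treatments = list(dict.fromkeys(ic25["treatment"]))
        profiles: dict[str, SensitivityProfile] = {}
        sens_rows = []
        for trt in treatments:
            sub = ic25[ic25["treatment"] == trt].set_index("cell_line")["ic25"]
            profiles[trt] = make_profile(trt, sub)
            for line, rank in profiles[trt].ranks.items():
                sens_rows.append(
                    {"cell_line": line, "treatment": trt,
                     "ic25": sub[line], "rank": rank}
                )
        io.write_tsv(pd.DataFrame(sens_rows), outdir / "sensitivity.tsv")
        pairs = {}
        ratios = {}
        for i, t1 in enumerate(treatments):
            for t2 in treatments[i + 1:]:
                res = cross_treatment_correlation(profiles[t1], profiles[t2])
                pairs[f"{t1} & {t2}"] = {"r": res.r, "p": res.p, "n": res.n}
                ratios[f"{t1}/{t2}"] = rank_ratio(profiles[t1], profiles[t2]).to_dict()
        sums = rank_sum(list(profiles.values())).to_dict() if len(profiles) >= 2 else {}
        metabolism = {}
        for trt, prof in profiles.items():
            try:
                m = correlate_metabolism(baseline, prof.ranks)
                metabolism[trt] = {"r": m.r, "p": m.p, "n": m.n}
            except ValidationError as exc:
                warnings.append(f"sensitivity_analysis: metabolism correlation "
                                f"for {trt} skipped ({exc})")
        cross = {
            "pairs": pairs,
            "rank_ratios": ratios,
            "rank_sums": sums,
            "dynamic_range": {t: profiles[t].dynamic_range for t in treatments},
            "baseline_metabolism_correlation": metabolism,
        }
        io.write_json(cross, outdir / "cross_treatment.json")

    with _stage("expression_prep"):
        matrix = average_replicates(samples, sheet)
        matrix = housekeeping_normalize(matrix, config.hk_gene)
        matrix = filter_annotated(matrix, annotation)
        counts["genes_after_annotation_filter"] = len(matrix.genes)
        symbols = annotation.set_index("gene_id")["symbol"].to_dict()

    with _stage("correlation_screen"):
        screens: dict[str, ScreenResult] = {}
        top_lists: dict[str, dict[str, list[str]]] = {}
        for trt in treatments:
            ic25_by_line = profiles[trt].ic25_by_line
            result = screen(matrix, ic25_by_line, trt,
                            alpha=config.alpha, p_method=config.p_method)
            screens[trt] = result
            tops = {
                "positive": select_top(result, config.k_signed, "positive"),
                "negative": select_top(result, config.k_signed, "negative"),
                "overall": select_top(result, config.k_overall, "overall"),
            }
            top_lists[trt] = tops
            rec = result.records.copy()
            rec["is_top20_pos"] = rec["gene"].isin(tops["positive"])
            rec["is_top20_neg"] = rec["gene"].isin(tops["negative"])
            rec["is_top500"] = rec["gene"].isin(tops["overall"])
            io.write_tsv(
                rec[["gene", "r", "p", "q", "n", "sign",
                     "is_top20_pos", "is_top20_neg", "is_top500"]],
                outdir / f"screen_{trt}.tsv",
            )
            for which, genes in tops.items():
                io.write_gene_list(
                    [str(symbols.get(g, g)) for g in genes],
                    outdir / "gene_lists" / f"{trt}_{which}.txt",
                )
            counts[f"significant_genes_{trt}"] = result.n_significant()
            if result.dropped:
                warnings.append(
                    f"correlation_screen[{trt}]: dropped {len(result.dropped)} genes"
                )

    with _stage("overlap_analysis"):
        universe = len(matrix.genes)
        overlaps: dict[str, dict] = {}
        for family, which in [("top20_positive", "positive"),
                              ("top20_negative", "negative"),
                              ("top500_overall", "overall")]:
            sets = [
                GeneSet.from_iterable(
                    f"{trt}_{which}",
                    [str(symbols.get(g, g)) for g in top_lists[trt][which]],
                )
                for trt in treatments
            ]
            report = overlap_report(sets, universe_size=universe)
            overlaps[family] = report.to_dict()
            for (a, b), (size, members, _p) in report.pairwise.items():
                io.write_tsv(
                    pd.DataFrame({"gene": members}),
                    outdir / "overlaps" / f"{family}__{a}__{b}.tsv",
                )
        io.write_json(overlaps, outdir / "overlap_report.json")

    manifest = {
        "package_version": _pkg_version("rospanel"),
        "seed": config.seed,
        "config": _config_echo(config),
        "row_counts": counts,
        "warnings": warnings,
    }
    io.write_json(manifest, outdir / "manifest.json")
    io.write_json(warnings, outdir / "warnings.json")
    return RunResult(
        outdir=outdir, ic25=ic25, profiles=profiles, cross_treatment=cross,
        matrix=matrix, screens=screens, top_lists=top_lists, overlaps=overlaps,
        manifest=manifest,
    )


def _config_echo(config: PipelineConfig) -> dict:
    d = asdict(config)
    if config.simulation is not None:
        d["simulation"] = asdict(config.simulation)
    return d
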