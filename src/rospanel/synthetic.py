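"""Synthetic oxidant-sensitivity panel generator with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a panel of cell lines (default 35) exposed to three oxidant
treatments — a gas-plasma jet titrated by exposure time (30/60/120 s),
H2O2 (1/10/100/1000 uM) and HOCl (0.1/1/10/100 mM) — whose latent
sensitivities are correlated across treatments (high plasma-H2O2
concordance, HOCl nearly independent), plus a basal expression matrix
in which configurable gene sets are planted to correlate with the
latent sensitivity of one or more treatments.

Rank-correlation structure is produced with a Gaussian copula: a target
Spearman correlation rho_S between two latent traits is converted to the
Pearson parameter of a bivariate normal via

    rho_P = 2 * sin(pi * rho_S / 6),

which is exact for the bivariate normal, so sample Spearman correlations
are calibrated to the targets. log10(IC25) is affine in the latent trait
(higher latent value = more resistant), anchored so the realized panel
spans the configured per-treatment log10 range — reproducing the
dynamic-range factors of the emulated study design (35-fold for plasma,
>1000-fold for H2O2, 64-fold for HOCl). Planted genes are linear in the
latent trait; since Spearman correlation is monotone-invariant, the
induced rank correlation with IC25 equals the one with the trait.

Randomness comes from one global seed; each stage draws from its own
substream so that, e.g., regenerating expression does not perturb the
dose-response noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from rospanel.errors import ValidationError

#: Fixed substream offsets per generation stage.
_STREAMS = {"latent": 1, "ic25": 2, "expression": 3, "dose_response": 4}


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson parameter of a bivariate normal with Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class TreatmentDesign:
    """One treatment's dose grid, unit, and target IC25 spread.

    ``ic25_log_range`` is the (lo, hi) of log10(IC25) in the treatment's
    dose unit that the panel should span.
    """

    name: str
    unit: str
    doses: tuple[float, ...]
    ic25_log_range: tuple[float, float]


@dataclass(frozen=True)
class PlantedSet:
    """A block of genes correlated with the sensitivity of >= 1 treatments.

    ``rho`` is the target Spearman correlation magnitude between the
    genes' per-line expression and IC25 (before replicate noise);
    ``sign`` is +1 (high expression in resistant lines) or -1.
    """

    treatments: tuple[str, ...]
    n_genes: int
    rho: float
    sign: int


def _default_treatments() -> tuple[TreatmentDesign, ...]:
    return (
        TreatmentDesign("plasma", "s", (30.0, 60.0, 120.0), (1.0, 1.0 + math.log10(35.0))),
        TreatmentDesign("h2o2", "uM", (1.0, 10.0, 100.0, 1000.0), (0.0, 3.1)),
        TreatmentDesign("hocl", "mM", (0.1, 1.0, 10.0, 100.0), (0.0, math.log10(64.0))),
    )


def _default_spearman_target() -> tuple[tuple[float, ...], ...]:
    # plasma-H2O2 strongly concordant; HOCl essentially independent
    return (
        (1.00, 0.64, 0.10),
        (0.64, 1.00, 0.02),
        (0.10, 0.02, 1.00),
    )


def _default_planted_sets() -> tuple[PlantedSet, ...]:
    return (
        PlantedSet(("plasma", "h2o2"), 40, 0.6, +1),
        PlantedSet(("plasma", "h2o2"), 40, 0.6, -1),
        PlantedSet(("plasma",), 60, 0.5, +1),
        PlantedSet(("plasma",), 60, 0.5, -1),
        PlantedSet(("h2o2",), 30, 0.5, +1),
        PlantedSet(("h2o2",), 30, 0.5, -1),
        PlantedSet(("hocl",), 25, 0.5, +1),
        PlantedSet(("hocl",), 25, 0.5, -1),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and noise levels of the simulated panel."""

    n_lines: int = 35
    treatments: tuple[TreatmentDesign, ...] = field(default_factory=_default_treatments)
    spearman_target: tuple[tuple[float, ...], ...] = field(
        default_factory=_default_spearman_target
    )
    n_genes: int = 2000
    planted_sets: tuple[PlantedSet, ...] = field(default_factory=_default_planted_sets)
    #: replicate-level technical noise on log2 expression
    expression_noise_sd: float = 0.25
    n_expr_replicates: int = 3
    hill_slope: float = 1.5
    viability_cv: float = 0.05
    n_dr_replicates: int = 3
    control_fluorescence_mean: float = 10000.0
    #: lognormal spread (log scale) of per-line control fluorescence
    control_line_sd: float = 0.15
    housekeeping_gene: str = "RPL13A"
    unannotated_fraction: float = 0.1
    seed: int = 0

    @property
    def treatment_names(self) -> list[str]:
        return [t.name for t in self.treatments]

    def validate(self) -> None:
        t = len(self.treatments)
        m = np.asarray(self.spearman_target, dtype=float)
        if m.shape != (t, t):
            raise ValidationError(
                f"spearman_target must be {t}x{t} for {t} treatments, got {m.shape}"
            )
        if not np.allclose(m, m.T):
            raise ValidationError("spearman_target must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValidationError("spearman_target must have unit diagonal")
        if np.abs(m).max() > 1.0:
            raise ValidationError("spearman_target entries must lie in [-1, 1]")
        for td in self.treatments:
            lo, hi = td.ic25_log_range
            if lo >= hi:
                raise ValidationError(
                    f"treatment {td.name}: ic25_log_range lo {lo} >= hi {hi}"
                )
            if any(d <= 0 for d in td.doses):
                raise ValidationError(f"treatment {td.name}: doses must be positive")
        n_planted = sum(ps.n_genes for ps in self.planted_sets)
        if n_planted + 1 > self.n_genes:  # +1 for the housekeeping gene
            raise ValidationError(
                f"{n_planted} planted genes + housekeeping exceed n_genes={self.n_genes}"
            )
        known = set(self.treatment_names)
        for ps in self.planted_sets:
            if not set(ps.treatments) <= known:
                raise ValidationError(f"planted set targets unknown treatments: {ps.treatments}")
            if abs(ps.rho) >= 1.0:
                raise ValidationError(f"planted effect size |rho| must be < 1, got {ps.rho}")
            if ps.sign not in (-1, +1):
                raise ValidationError(f"planted sign must be +1/-1, got {ps.sign}")
        for name, value in [
            ("expression_noise_sd", self.expression_noise_sd),
            ("viability_cv", self.viability_cv),
            ("unannotated_fraction", self.unannotated_fraction),
        ]:
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.hill_slope <= 0 or self.control_fluorescence_mean <= 0:
            raise ValidationError("hill_slope and control_fluorescence_mean must be > 0")
        if self.n_lines < 3 or self.n_expr_replicates < 1 or self.n_dr_replicates < 1:
            raise ValidationError("n_lines >= 3 and replicate counts >= 1 required")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for validation downstream."""

    latent_sensitivity: pd.DataFrame  # lines x treatments, standard normal
    true_ic25: pd.DataFrame  # lines x treatments, dose units
    #: columns gene, treatments ('+'-joined), true_rho, sign
    planted_gene_table: pd.DataFrame


@dataclass(frozen=True)
class SimulatedPanel:
    """Complete synthetic input dataset plus its ground truth."""

    config: SimulationConfig
    dose_response: pd.DataFrame
    expression_samples: pd.DataFrame
    sample_sheet: pd.DataFrame
    annotation: pd.DataFrame
    truth: GroundTruth


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stage], config.seed])


def _line_ids(n: int) -> list[str]:
    return [f"CL{i + 1:03d}" for i in range(n)]


def simulate_latent(config: SimulationConfig) -> pd.DataFrame:
    """Draw latent sensitivities from a Gaussian copula.

    Returns an n_lines x treatments matrix with standard-normal margins
    whose pairwise Spearman correlations are calibrated to
    ``config.spearman_target``. Higher values mean more resistant.
    """
    config.validate()
    target = np.asarray(config.spearman_target, dtype=float)
    pearson = 2.0 * np.sin(np.pi * target / 6.0)
    np.fill_diagonal(pearson, 1.0)
    eigvals, eigvecs = np.linalg.eigh(pearson)
    if eigvals.min() < -1e-10:
        raise ValidationError(
            "spearman_target is not positive semidefinite after conversion to "
            f"Pearson scale: smallest eigenvalue {eigvals.min():.3e}"
        )
    factor = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    rng = _rng(config, "latent")
    z = rng.standard_normal((config.n_lines, len(config.treatments))) @ factor.T
    return pd.DataFrame(z, index=_line_ids(config.n_lines), columns=config.treatment_names)


def simulate_ic25(latent: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Map latent sensitivity to IC25 per treatment (dose units).

    log10(IC25) is affine in the latent trait with positive slope,
    anchored so the realized panel minimum and maximum hit the
    configured ``ic25_log_range`` endpoints. A degenerate (constant)
    latent column maps to the range midpoint.
    """
    config.validate()
    out = {}
    for td in config.treatments:
        z = latent[td.name].to_numpy(dtype=float)
        lo, hi = td.ic25_log_range
        span = z.max() - z.min()
        if span == 0:
            log_ic25 = np.full_like(z, (lo + hi) / 2.0)
        else:
            log_ic25 = lo + (z - z.min()) / span * (hi - lo)
        out[td.name] = 10.0**log_ic25
    return pd.DataFrame(out, index=latent.index)


def _planted_effect_matrix(
    latent: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Per-line true values for planted genes plus the ground-truth table."""
    n_planted = sum(ps.n_genes for ps in config.planted_sets)
    pearson = 2.0 * np.sin(np.pi * np.asarray(config.spearman_target, float) / 6.0)
    np.fill_diagonal(pearson, 1.0)
    names = config.treatment_names
    values = np.empty((n_planted, config.n_lines))
    table_rows = []
    gene_ids = []
    i = 0
    gene_no = 0
    for ps in config.planted_sets:
        idx = [names.index(t) for t in ps.treatments]
        # standardized mean of the targeted treatments' latent traits
        w = latent.iloc[:, idx].to_numpy().mean(axis=1)
        var = pearson[np.ix_(idx, idx)].mean()  # Var(mean) for unit-variance margins
        zbar = w / math.sqrt(var)
        # Spearman effect -> Pearson slope on the latent scale
        rho_p = spearman_to_pearson(ps.rho)
        beta = rho_p / math.sqrt(1.0 - rho_p**2)
        for _ in range(ps.n_genes):
            gene_no += 1
            gid = f"PL{gene_no:04d}"
            gene_ids.append(gid)
            eps = rng.standard_normal(config.n_lines)
            values[i] = ps.sign * beta * zbar + eps
            table_rows.append(
                {"gene": gid, "treatments": "+".join(ps.treatments),
                 "true_rho": ps.rho, "sign": "+" if ps.sign > 0 else "-"}
            )
            i += 1
    table = pd.DataFrame(table_rows, columns=["gene", "treatments", "true_rho", "sign"])
    return values, table, gene_ids


def simulate_expression(
    latent: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate replicate-level expression samples with planted signal.

    Returns (samples, sample_sheet, annotation, truth). ``samples`` is a
    genes x samples log2 matrix with ``n_expr_replicates`` samples per
    line. Planted genes follow x = sign * beta * z + eps on standardized
    scales with beta set so the expected Spearman correlation with the
    targeted treatment's IC25 equals the configured effect size;
    background genes are pure noise; the housekeeping gene is constant
    across lines up to a small replicate noise. The annotation table
    leaves a configurable fraction of background genes unannotated
    (empty symbol).
    """
    config.validate()
    rng = _rng(config, "expression")
    lines = list(latent.index)
    n_lines = len(lines)

    planted_vals, planted_table, planted_ids = _planted_effect_matrix(latent, config, rng)
    n_planted = len(planted_ids)
    n_background = config.n_genes - n_planted - 1  # minus housekeeping

    hk = config.housekeeping_gene
    bg_ids = [f"BG{i + 1:04d}" for i in range(n_background)]
    gene_ids = [hk] + planted_ids + bg_ids

    # per-gene baseline abundance (log2 a.u.); housekeeping pinned at 8
    baselines = np.concatenate(
        [[8.0], rng.uniform(4.0, 12.0, size=n_planted + n_background)]
    )
    per_line = np.empty((config.n_genes, n_lines))
    per_line[0] = 0.0  # housekeeping: constant across lines
    per_line[1 : 1 + n_planted] = planted_vals
    per_line[1 + n_planted :] = rng.standard_normal((n_background, n_lines))

    sample_ids = []
    sheet_rows = []
    cols = []
    for j, line in enumerate(lines):
        for rep in range(1, config.n_expr_replicates + 1):
            sid = f"{line}_r{rep}"
            sample_ids.append(sid)
            sheet_rows.append({"sample_id": sid, "cell_line": line, "replicate": rep})
            noise = rng.normal(0.0, config.expression_noise_sd, size=config.n_genes)
            # housekeeping replicate noise kept small relative to other genes
            noise[0] *= 0.2
            cols.append(baselines + per_line[:, j] + noise)
    samples = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )
    sample_sheet = pd.DataFrame(sheet_rows)

    n_unann = round(config.unannotated_fraction * config.n_genes)
    if n_unann > n_background:
        raise ValidationError(
            f"unannotated fraction requires {n_unann} background genes, have {n_background}"
        )
    unannotated = set(rng.choice(bg_ids, size=n_unann, replace=False)) if n_unann else set()
    annotation = pd.DataFrame(
        {"gene_id": gene_ids,
         "symbol": [("" if g in unannotated else g) for g in gene_ids]}
    )
    truth = GroundTruth(
        latent_sensitivity=latent,
        true_ic25=simulate_ic25(latent, config),
        planted_gene_table=planted_table,
    )
    return samples, sample_sheet, annotation, truth


def simulate_dose_response(true_ic25: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Generate raw fluorescence readouts from the true dose-response curves.

    fluorescence = control_mean(line) * v(dose) * noise, with
    v(d) = 1/(1 + (d/EC50)^h), EC50 chosen so the curve's IC25 equals
    ``true_ic25``, and multiplicative lognormal noise of coefficient of
    variation ``viability_cv`` (mean 1). Includes dose-0 control rows.
    """
    config.validate()
    rng = _rng(config, "dose_response")
    h = config.hill_slope
    cv = config.viability_cv
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0

    lines = list(true_ic25.index)
    line_ctrl = config.control_fluorescence_mean * np.exp(
        rng.normal(0.0, config.control_line_sd, size=len(lines))
    )
    rows = []
    for j, line in enumerate(lines):
        for td in config.treatments:
            ec50 = true_ic25.loc[line, td.name] * 3.0 ** (1.0 / h)
            for dose in (0.0, *td.doses):
                v = 1.0 if dose == 0 else 1.0 / (1.0 + (dose / ec50) ** h)
                for rep in range(1, config.n_dr_replicates + 1):
                    noise = (
                        math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                    )
                    rows.append(
                        {"cell_line": line, "treatment": td.name, "dose": dose,
                         "unit": td.unit, "replicate": rep,
                         "fluorescence": line_ctrl[j] * v * noise}
                    )
    return pd.DataFrame(rows)


def simulate_panel(config: SimulationConfig | None = None) -> SimulatedPanel:
    """Generate the full synthetic panel: all pipeline inputs + truth."""
    config = config or SimulationConfig()
    config.validate()
    latent = simulate_latent(config)
    samples, sheet, annotation, truth = simulate_expression(latent, config)
    dr = simulate_dose_response(truth.true_ic25, config)
    return SimulatedPanel(
        config=config, dose_response=dr, expression_samples=samples,
        sample_sheet=sheet, annotation=annotation, truth=truth,
    )


def write_panel(panel: SimulatedPanel, outdir: str | Path) -> dict[str, Path]:
    """Write the panel's input files and ground truth to ``outdir``.

    Emits dose_response.csv, expression.tsv, sample_sheet.csv,
    annotation.tsv, ground_truth.tsv and config.json; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dose_response": outdir / "dose_response.csv",
        "expression": outdir / "expression.tsv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "annotation": outdir / "annotation.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "config": outdir / "config.json",
    }
    panel.dose_response.to_csv(paths["dose_response"], index=False)
    panel.expression_samples.to_csv(paths["expression"], sep="\t")
    panel.sample_sheet.to_csv(paths["sample_sheet"], index=False)
    panel.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    panel.truth.planted_gene_table.to_csv(paths["ground_truth"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(asdict(panel.config), indent=2, default=list) + "\n")
    return paths
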