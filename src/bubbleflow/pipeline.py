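"""End-to-end orchestration: synthesise (or load) paired sub-aperture
acquisitions, clutter-filter, form ASAP images, extract and fit TICs,
derive perfusion parameters, and compare agent arms across a cohort.

The cohort design mirrors a paired molecular-imaging study: every
subject receives both the non-targeted and the targeted agent (each
animal serving as its own control), so arm comparisons are paired within
subject.  Injection-to-injection variability is modelled as lognormal
jitter on the bolus amplitude and shape parameters plus Gaussian jitter
on the arrival time, independently for each injection.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as bfio
from .clutter import asap_correlation, svd_clutter_filter
from .containers import FrameStack, PerfusionParameters
from .errors import InvalidConfigurationError, InvalidInputError
from .kinetics import derive_parameters, extract_tic, fit_gamma_variate
from .synthetic import BolusParams, RetentionParams, SceneConfig, generate_ceus_scene, generate_tic, generate_retention_tic

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "CohortResult",
    "analyze_stack_pair",
    "run_synthetic_experiment",
    "simulate_tic_cohort",
    "compare_groups",
    "significance_stars",
]

ARMS = ("non-targeted", "targeted")
DEFAULT_PARAMS = list(PerfusionParameters.PARAM_NAMES)


@dataclass
class RunConfig:
    """Configuration of a synthetic cohort run.

    ``amplitude_cv`` is the per-injection lognormal coefficient of
    variation on the bolus amplitude (dose and injection-speed
    variability — the reason TICs are conventionally peak-normalised);
    ``subject_shape_cv`` varies (alpha, beta) between subjects (vascular
    physiology, shared by both arms of a subject) and
    ``injection_shape_cv`` adds a small within-subject shape jitter per
    injection; ``t0_jitter_sd`` (s) perturbs the arrival lag per
    injection.  The targeted arm adds the bound-pool retention component.
    """

    n_subjects: int = 6
    groups: tuple[str, ...] = ("tumor",)
    scene: SceneConfig = field(default_factory=SceneConfig)
    targeted_retention: RetentionParams | None = field(
        default_factory=RetentionParams
    )
    amplitude_cv: float = 0.2
    subject_shape_cv: float = 0.1
    injection_shape_cv: float = 0.03
    t0_jitter_sd: float = 2.0
    low_cutoff: int | None = None  # default: the scene's clutter rank
    arrival_threshold: float = 0.1
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigurationError("n_subjects must be >= 1")
        for cv in (self.amplitude_cv, self.subject_shape_cv,
                   self.injection_shape_cv):
            if cv < 0:
                raise InvalidConfigurationError("jitter CVs must be >= 0")
        if self.t0_jitter_sd < 0:
            raise InvalidConfigurationError("t0_jitter_sd must be >= 0")


@dataclass
class CohortResult:
    """Per-subject perfusion parameters for each arm plus exclusions."""

    table: pd.DataFrame  # columns: subject, group, arm, converged, params...
    n_excluded: int = 0

    def summary(self) -> pd.DataFrame:
        """Group x arm means and standard errors per parameter."""
        ok = self.table[self.table["converged"]]
        agg = ok.groupby(["group", "arm"])[DEFAULT_PARAMS].agg(["mean", "sem"])
        return agg


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


def _subject_bolus(base: BolusParams, rng: np.random.Generator,
                   subject_shape_cv: float) -> BolusParams:
    """Subject-level physiology: shared bolus shape for both arms."""
    return dataclasses.replace(
        base,
        alpha=base.alpha * _lognormal_factor(rng, subject_shape_cv),
        beta=base.beta * _lognormal_factor(rng, subject_shape_cv),
    )


def _jittered_bolus(base: BolusParams, rng: np.random.Generator,
                    amplitude_cv: float, shape_cv: float,
                    t0_jitter_sd: float, seed: int) -> tuple[BolusParams, float]:
    """One injection's bolus parameters and its amplitude factor."""
    amp = _lognormal_factor(rng, amplitude_cv)
    params = BolusParams(
        A=base.A,
        alpha=base.alpha * _lognormal_factor(rng, shape_cv),
        beta=base.beta * _lognormal_factor(rng, shape_cv),
        t0=max(0.0, base.t0 + float(rng.normal(0.0, t0_jitter_sd))),
        noise_sd=base.noise_sd,
        seed=seed,
    )
    return params, amp


def analyze_stack_pair(stack_a: FrameStack, stack_b: FrameStack,
                       mask: np.ndarray, low_cutoff: int = 2,
                       arrival_threshold: float = 0.1) -> dict:
    """Filter both sub-apertures, form the ASAP image, extract the ROI
    TIC and fit the bolus model.

    The ROI trace is the mean of the two filtered apertures' power
    curves converted to envelope amplitude (square root), matching the
    B-mode convention in which TICs are amplitude-scaled; the fit uses
    the first-pass window so late retention cannot bias the bolus shape.

    Returns a dict with keys ``asap``, ``tic``, ``fit`` and ``params``
    (``params`` is None when the fit does not converge).
    """
    filt_a = svd_clutter_filter(stack_a, low_cutoff=low_cutoff)
    filt_b = svd_clutter_filter(stack_b, low_cutoff=low_cutoff)
    asap = asap_correlation(filt_a, filt_b, normalized=True)
    tic_a = extract_tic(filt_a, mask)
    tic_b = extract_tic(filt_b, mask)
    from .containers import TimeIntensityCurve

    power = (tic_a.intensities + tic_b.intensities) / 2.0
    tic = TimeIntensityCurve(tic_a.times, np.sqrt(np.clip(power, 0.0, None)))
    fit = fit_gamma_variate(tic, fit_t0=True, window="first-pass")
    params = (
        derive_parameters(fit, tic, arrival_threshold=arrival_threshold)
        if fit.converged else None
    )
    return {"asap": asap, "tic": tic, "fit": fit, "params": params}


def _result_row(subject: str, group: str, arm: str, fit, params) -> dict:
    row = {"subject": subject, "group": group, "arm": arm,
           "converged": bool(fit.converged)}
    if params is not None:
        row.update(params.as_dict())
    else:
        row.update({name: np.nan for name in DEFAULT_PARAMS})
    return row


def run_synthetic_experiment(config: RunConfig) -> CohortResult:
    """Generate and analyse a full paired synthetic cohort.

    For each subject and arm: generate the paired sub-aperture scene,
    SVD-filter both stacks, save the ASAP correlation image, extract and
    fit the ROI TIC and derive the perfusion parameters.  Fully
    reproducible from ``(config, config.seed)``; non-converged fits are
    kept in the table flagged ``converged=False`` and excluded from the
    statistics.
    """
    rng = np.random.default_rng(config.seed)
    low_cutoff = (config.low_cutoff if config.low_cutoff is not None
                  else config.scene.clutter_rank)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    try:
        for group in config.groups:
            for s in range(config.n_subjects):
                subject = f"{group}-s{s:02d}"
                subject_bolus = _subject_bolus(config.scene.bolus, rng,
                                               config.subject_shape_cv)
                for arm in ARMS:
                    try:
                        bolus, amp = _jittered_bolus(
                            subject_bolus, rng, config.amplitude_cv,
                            config.injection_shape_cv, config.t0_jitter_sd,
                            seed=int(rng.integers(2**31)),
                        )
                        retention = (config.targeted_retention
                                     if arm == "targeted" else None)
                        scene = dataclasses.replace(
                            config.scene, bolus=bolus, retention=retention,
                            flow_amplitude=config.scene.flow_amplitude * amp,
                            seed=int(rng.integers(2**31)),
                        )
                        stack_a, stack_b, truth = generate_ceus_scene(scene)
                        res = analyze_stack_pair(
                            stack_a, stack_b, truth["vessel_mask"],
                            low_cutoff=low_cutoff,
                            arrival_threshold=config.arrival_threshold,
                        )
                        rows.append(_result_row(subject, group, arm,
                                                res["fit"], res["params"]))
                        if out_dir:
                            stem = out_dir / f"{subject}_{arm}"
                            bfio.save_doppler_image(res["asap"],
                                                    stem.with_suffix(".asap.tif"))
                            bfio.save_tic(res["tic"], stem.with_suffix(".tic.csv"))
                            bfio.save_fit(res["fit"], stem.with_suffix(".fit.json"))
                    except Exception as exc:
                        raise RuntimeError(
                            f"stage failed for subject={subject} arm={arm}: {exc}"
                        ) from exc
    finally:
        # flush whatever completed before any abort
        if out_dir and rows:
            _write_cohort_table(rows, out_dir / "cohort.csv")

    table = pd.DataFrame(rows)
    n_excluded = int((~table["converged"]).sum())
    if n_excluded:
        logger.warning("%d non-converged fits excluded from statistics",
                       n_excluded)
    result = CohortResult(table=table, n_excluded=n_excluded)
    if out_dir:
        stats_df = None
        if config.n_subjects >= 2:
            stats_df = compare_groups(result)
            stats_df.to_csv(out_dir / "statistics.csv", index=False,
                            float_format="%.17g")
        _write_report(config, result, stats_df, out_dir / "report.txt")
    return result


def _write_cohort_table(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def _write_report(config: RunConfig, result: CohortResult,
                  stats_df: pd.DataFrame | None, path: Path) -> None:
    lines = [
        "bubbleflow synthetic cohort report",
        f"seed: {config.seed}",
        f"groups: {', '.join(config.groups)}  subjects/group: {config.n_subjects}",
        f"scene: grid={config.scene.grid_shape} rate={config.scene.frame_rate} Hz "
        f"duration={config.scene.duration} s clutter_rank={config.scene.clutter_rank}",
        f"retention (targeted arm): {config.targeted_retention}",
        f"fits excluded (non-converged): {result.n_excluded}",
        "",
        stats_df.to_string(index=False) if stats_df is not None
        else "(too few subjects for statistics)",
        "",
    ]
    path.write_text("\n".join(lines))


def simulate_tic_cohort(config: RunConfig, frame_rate: float | None = None,
                        duration: float | None = None) -> CohortResult:
    """TIC-level paired cohort: same design as
    :func:`run_synthetic_experiment` but sampling the ROI curves directly
    from the bolus model, skipping scene synthesis and clutter filtering.
    Useful for statistical calibration at scale.
    """
    rng = np.random.default_rng(config.seed)
    frame_rate = frame_rate or config.scene.frame_rate
    duration = duration or config.scene.duration
    rows: list[dict] = []
    for group in config.groups:
        for s in range(config.n_subjects):
            subject = f"{group}-s{s:02d}"
            subject_bolus = _subject_bolus(config.scene.bolus, rng,
                                           config.subject_shape_cv)
            for arm in ARMS:
                bolus, amp = _jittered_bolus(
                    subject_bolus, rng, config.amplitude_cv,
                    config.injection_shape_cv, config.t0_jitter_sd,
                    seed=int(rng.integers(2**31)),
                )
                bolus = dataclasses.replace(bolus, A=bolus.A * amp)
                retention = (config.targeted_retention
                             if arm == "targeted" else None)
                if retention is None:
                    tic, _ = generate_tic(bolus, frame_rate, duration)
                else:
                    tic, _ = generate_retention_tic(bolus, retention,
                                                    frame_rate, duration)
                fit = fit_gamma_variate(tic, fit_t0=True, window="first-pass")
                params = (derive_parameters(fit, tic,
                                            config.arrival_threshold)
                          if fit.converged else None)
                rows.append(_result_row(subject, group, arm, fit, params))
    table = pd.DataFrame(rows)
    return CohortResult(table=table,
                        n_excluded=int((~table["converged"]).sum()))


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Significance convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _safe_paired_t(diff: np.ndarray) -> tuple[float, float]:
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        return float("inf"), 0.0
    res = stats.ttest_1samp(diff, 0.0)
    return float(res.statistic), float(res.pvalue)


def _safe_unpaired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float("inf"), 0.0
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_groups(result: CohortResult | pd.DataFrame,
                   design: str = "paired",
                   correction: str = "bonferroni",
                   parameters: list[str] | None = None) -> pd.DataFrame:
    """Arm comparison (targeted vs non-targeted) per perfusion parameter.

    Parameters
    ----------
    design : {"paired", "unpaired", "two-factor"}
        ``paired`` — within-subject t-test on arm differences (each
        subject its own control); ``unpaired`` — two-sample t-test;
        ``two-factor`` — two-way ANOVA (arm x group) reporting the arm
        main effect alongside the group and interaction p-values.
    correction : {"none", "bonferroni"}
        Bonferroni multiplies each raw p by the number of parameters
        tested, capped at 1.

    Returns a DataFrame with one row per parameter: statistic, raw and
    corrected p, and significance stars (* 0.05, ** 0.01, *** 0.001).
    """
    table = result.table if isinstance(result, CohortResult) else result
    table = table[table["converged"]] if "converged" in table else table
    parameters = parameters or DEFAULT_PARAMS
    if design not in ("paired", "unpaired", "two-factor"):
        raise InvalidInputError(f"unknown design {design!r}")
    if correction not in ("none", "bonferroni"):
        raise InvalidInputError(f"unknown correction {correction!r}")

    rows = []
    for name in parameters:
        extra: dict[str, float] = {}
        if design == "paired":
            wide = table.pivot_table(index="subject", columns="arm",
                                     values=name, aggfunc="first")
            if wide.isna().any().any() or wide.shape[1] != 2:
                raise InvalidInputError(
                    "paired design needs both arms for every subject"
                )
            if wide.shape[0] < 2:
                raise InvalidInputError("need at least 2 subjects per cell")
            diff = (wide["targeted"] - wide["non-targeted"]).to_numpy()
            stat, p = _safe_paired_t(diff)
            extra["mean_difference"] = float(diff.mean())
        elif design == "unpaired":
            a = table.loc[table["arm"] == ARMS[1], name].to_numpy()
            b = table.loc[table["arm"] == ARMS[0], name].to_numpy()
            if min(a.size, b.size) < 2:
                raise InvalidInputError("need at least 2 observations per cell")
            stat, p = _safe_unpaired_t(a, b)
            extra["mean_difference"] = float(a.mean() - b.mean())
        else:  # two-factor ANOVA: arm x group
            import statsmodels.api as sm
            from statsmodels.formula.api import ols

            sub = table[["arm", "group", name]].rename(columns={name: "y"})
            if sub.groupby(["arm", "group"]).size().min() < 2:
                raise InvalidInputError("need at least 2 observations per cell")
            model = ols("y ~ C(arm) * C(group)", data=sub).fit()
            anova = sm.stats.anova_lm(model, typ=2)
            stat = float(anova.loc["C(arm)", "F"])
            p = float(anova.loc["C(arm)", "PR(>F)"])
            extra["p_group"] = float(anova.loc["C(group)", "PR(>F)"])
            extra["p_interaction"] = float(anova.loc["C(arm):C(group)", "PR(>F)"])

        rows.append({"parameter": name, "design": design, "statistic": stat,
                     "p_raw": p, **extra})

    df = pd.DataFrame(rows)
    m = len(parameters)
    if correction == "bonferroni":
        df["p_corrected"] = np.minimum(1.0, m * df["p_raw"])
    else:
        df["p_corrected"] = df["p_raw"]
    df["significance"] = df["p_corrected"].map(significance_stars)
    return df
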