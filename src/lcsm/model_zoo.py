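"""Builders for the study's model specifications.

Three accounts of coupled cognitive development over three waves of
vocabulary and matrix-reasoning scores, expressed as latent change score
(LCS) models, plus two alternative specifications:

* **mutualism** — bivariate LCS with free bidirectional couplings: each
  domain's change depends on the *other* domain's prior level.
* **investment** — same model with only the reasoning -> vocabulary-change
  coupling free (fluid ability invested into crystallized knowledge).
* **g-factor** — one common factor per wave (measurement-invariant
  loadings/intercepts) developing as a univariate LCS.
* **parallel-process** — bivariate latent growth model whose slope factors
  are regressed on the other domain's intercept factor.
* **RI-CLPM** — random-intercept cross-lagged panel model separating stable
  between-person differences from within-person lagged dynamics.

Single indicators are given a latent true-score layer whose observed
residual variance is fixed to S^2 (1 - Rxx), the sample variance times one
minus the internal-consistency reliability; without reliabilities the
indicators are treated as error-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .sem_core import ModelSpec, Param, SemError, _covkey, fixed, free

DEFAULT_DOMAINS = ("vocabulary", "reasoning")
DEFAULT_WAVES = ("T1", "T2", "T3")


class DesignError(SemError):
    """The study design is outside what a builder supports."""


@dataclass(frozen=True)
class StudyDesign:
    """Observed-data facts the builders need.

    ``variances`` (sample variances, used both for the reliability
    adjustment and for starting values) and optional ``means`` are keyed by
    domain then wave.  ``reliabilities`` holds internal-consistency Rxx per
    domain and wave; ``None`` treats single indicators as error-free.
    """

    wave_labels: tuple[str, ...] = DEFAULT_WAVES
    domains: tuple[str, str] = DEFAULT_DOMAINS
    reliabilities: Mapping[str, Mapping[str, float]] | None = None
    variances: Mapping[str, Mapping[str, float]] | None = None
    means: Mapping[str, Mapping[str, float]] | None = None
    slope_loadings: tuple[float, ...] = (0.0, 1.0, 2.0)

    def __post_init__(self):
        if self.reliabilities is not None:
            for d, per_wave in self.reliabilities.items():
                for w, r in per_wave.items():
                    if not (0.0 < r <= 1.0):
                        raise DesignError(
                            f"reliability for {d}/{w} must be in (0, 1], got {r}"
                        )
        if any(
            b <= a for a, b in zip(self.slope_loadings, self.slope_loadings[1:])
        ):
            raise DesignError("slope loadings must be strictly increasing")

    @property
    def n_waves(self) -> int:
        return len(self.wave_labels)

    def variance(self, domain: str, wave: str) -> float:
        if self.variances is None:
            return 1.0
        return float(self.variances[domain][wave])

    def mean(self, domain: str, wave: str) -> float:
        if self.means is None:
            return 0.0
        return float(self.means[domain][wave])

    def residual(self, domain: str, wave: str) -> float:
        """Fixed measurement residual S^2 (1 - Rxx) for one indicator."""
        if self.reliabilities is None:
            return 0.0
        return reliability_residual_variance(
            self.variance(domain, wave), float(self.reliabilities[domain][wave])
        )


def design_from_data(data, reliabilities=None, slope_loadings=(0.0, 1.0, 2.0)) -> StudyDesign:
    """Derive a StudyDesign (variances, means) from a LongitudinalDataset."""
    variances = {d: {} for d in data.domain_labels}
    means = {d: {} for d in data.domain_labels}
    for d in data.domain_labels:
        for w in data.wave_labels:
            col = f"{d}_{w}"
            variances[d][w] = float(data.scores[col].var())
            means[d][w] = float(data.scores[col].mean())
    return StudyDesign(
        wave_labels=tuple(data.wave_labels),
        domains=tuple(data.domain_labels),
        reliabilities=reliabilities,
        variances=variances,
        means=means,
        slope_loadings=tuple(slope_loadings),
    )


def reliability_residual_variance(s2: float, rxx: float) -> float:
    """Fixed residual variance S^2 (1 - Rxx) of a single-indicator latent.

    ``s2`` is the indicator's sample variance and ``rxx`` its
    internal-consistency reliability.
    """
    if s2 <= 0:
        raise ValueError(f"sample variance must be positive, got {s2}")
    if not (0.0 < rxx <= 1.0):
        raise ValueError(f"reliability must be in (0, 1], got {rxx}")
    return s2 * (1.0 - rxx)


# ---------------------------------------------------------------------------
# Shared pieces
# ---------------------------------------------------------------------------


def _require_three_waves(design: StudyDesign, builder: str):
    if design.n_waves != 3:
        raise DesignError(
            f"{builder} supports exactly 3 waves (got {design.n_waves}); "
            "generalizing the wave count is a documented extension point"
        )


def _measurement_layer(design: StudyDesign, paths, covs):
    """Observed indicator <- latent true score with reliability-fixed residual."""
    for d in design.domains:
        for w in design.wave_labels:
            obs, true = f"{d}_{w}", f"{d}_{w}_true"
            paths[(true, obs)] = fixed(1.0)
            covs[_covkey(obs, obs)] = fixed(design.residual(d, w), f"resid_{d}_{w}")


def _cov(covs, a, b, param):
    covs[_covkey(a, b)] = param


# ---------------------------------------------------------------------------
# Latent change score builders
# ---------------------------------------------------------------------------


def build_bivariate_lcs(
    design: StudyDesign,
    *,
    couplings: Sequence[tuple[str, str]] = (),
    free_first_domain_change_intercept: bool = True,
    name: str = "bivariate_lcs",
) -> ModelSpec:
    """Bivariate LCS over three waves with configurable coupling directions.

    ``couplings`` lists (source_domain, target_domain) pairs whose coupling
    path (source's prior level -> target's change) is free; all other
    cross-domain couplings are present but fixed to 0 so they can be freed
    or tested later.  Self-feedbacks, couplings and change residual
    variances are equated across waves; the first domain's change intercept
    is freed per occasion by default (the model's one departure from full
    cross-wave equality), as is conventional when conditional gains shrink
    over occasions.
    """
    _require_three_waves(design, name)
    dA, dB = design.domains
    waves = design.wave_labels
    free_set = {tuple(c) for c in couplings}

    paths: dict = {}
    covs: dict = {}
    means: dict = {}
    _measurement_layer(design, paths, covs)

    change_vars: dict[str, list[str]] = {d: [] for d in design.domains}
    for d in design.domains:
        other = dB if d == dA else dA
        t1 = f"{d}_{waves[0]}_true"
        _cov(covs, t1, t1, free(f"var_{d}_{waves[0]}", design.variance(d, waves[0]) / 2))
        means[t1] = free(f"mean_{d}_{waves[0]}", design.mean(d, waves[0]))
        for k in range(1, 3):
            prev, cur = f"{d}_{waves[k-1]}_true", f"{d}_{waves[k]}_true"
            ch = f"d_{d}_{waves[k]}"
            change_vars[d].append(ch)
            paths[(prev, cur)] = fixed(1.0)
            paths[(ch, cur)] = fixed(1.0)
            paths[(prev, ch)] = free(f"beta_{d}", 0.0)
            glab = f"gamma_{other}_to_{d}"
            src = f"{other}_{waves[k-1]}_true"
            paths[(src, ch)] = (
                free(glab, 0.0) if (other, d) in free_set else Param(0.0, glab, False)
            )
            _cov(covs, ch, ch, free(f"zeta_{d}", design.variance(d, waves[k]) / 4))
            gain = design.mean(d, waves[k]) - design.mean(d, waves[k - 1])
            if d == dA and free_first_domain_change_intercept:
                means[ch] = free(f"alpha_{d}_{waves[k]}", gain)
            else:
                means[ch] = free(f"alpha_{d}", gain)
    _cov(
        covs,
        f"{dA}_{waves[0]}_true",
        f"{dB}_{waves[0]}_true",
        free(
            f"cov_{dA}_{dB}_{waves[0]}",
            0.5
            * (design.variance(dA, waves[0]) * design.variance(dB, waves[0])) ** 0.5
            / 2,
        ),
    )
    # change-score covariances: contemporaneous equated across waves, the
    # four lagged covariances individually free
    for k in range(2):
        _cov(
            covs,
            change_vars[dA][k],
            change_vars[dB][k],
            free("psi_change_contemp", 0.0),
        )
    for d in design.domains:
        a, b = change_vars[d]
        _cov(covs, a, b, free(f"psi_lag_{d}", 0.0))
    _cov(covs, change_vars[dA][0], change_vars[dB][1], free(f"psi_lag_{dA}_{dB}", 0.0))
    _cov(covs, change_vars[dB][0], change_vars[dA][1], free(f"psi_lag_{dB}_{dA}", 0.0))

    variables = (
        [f"{d}_{w}" for d in design.domains for w in waves]
        + [f"{d}_{w}_true" for d in design.domains for w in waves]
        + [c for d in design.domains for c in change_vars[d]]
    )
    observed = tuple(f"{d}_{w}" for d in design.domains for w in waves)
    return ModelSpec(name, tuple(variables), observed, paths, covs, means)


def build_mutualism_lcs(
    design: StudyDesign, *, free_vocab_change_intercept: bool = True
) -> ModelSpec:
    """Mutualism: bidirectional cross-domain couplings free (df = 8)."""
    dA, dB = design.domains
    return build_bivariate_lcs(
        design,
        couplings=((dA, dB), (dB, dA)),
        free_first_domain_change_intercept=free_vocab_change_intercept,
        name="mutualism_lcs",
    )


def build_investment_lcs(
    design: StudyDesign,
    *,
    direction: tuple[str, str] | None = None,
    free_vocab_change_intercept: bool = True,
) -> ModelSpec:
    """Investment: one coupling direction free, the other fixed to 0.

    Default direction is reasoning -> vocabulary change (fluid ability
    invested into crystallized knowledge); pass ``direction`` to flip.
    """
    if direction is None:
        direction = (design.domains[1], design.domains[0])
    return build_bivariate_lcs(
        design,
        couplings=(direction,),
        free_first_domain_change_intercept=free_vocab_change_intercept,
        name="investment_lcs",
    )


def build_no_coupling_lcs(
    design: StudyDesign, *, free_vocab_change_intercept: bool = True
) -> ModelSpec:
    """Bivariate LCS with both couplings fixed to 0 (null dynamics)."""
    return build_bivariate_lcs(
        design,
        couplings=(),
        free_first_domain_change_intercept=free_vocab_change_intercept,
        name="no_coupling_lcs",
    )


def build_gfactor_lcs(design: StudyDesign) -> ModelSpec:
    """One common factor per wave developing as a univariate LCS.

    Measurement invariance is imposed: the factor loading and measurement
    intercept of each indicator are equated across waves.  The first
    domain's indicator fixes the factor scale (loading 1, intercept 0).
    """
    _require_three_waves(design, "g-factor LCS")
    dA, dB = design.domains
    waves = design.wave_labels
    paths: dict = {}
    covs: dict = {}
    means: dict = {}
    _measurement_layer(design, paths, covs)

    for w in waves:
        g = f"g_{w}"
        paths[(g, f"{dA}_{w}_true")] = fixed(1.0)
        paths[(g, f"{dB}_{w}_true")] = free(f"lambda_{dB}", 1.0)
        means[f"{dB}_{w}_true"] = free(f"tau_{dB}", design.mean(dB, w) - design.mean(dA, w))
        for d in design.domains:
            t = f"{d}_{w}_true"
            _cov(covs, t, t, free(f"uniq_{d}", design.variance(d, w) / 4))

    g1 = f"g_{waves[0]}"
    _cov(covs, g1, g1, free("var_g", design.variance(dA, waves[0]) / 2))
    means[g1] = free("mean_g", design.mean(dA, waves[0]))
    changes = []
    for k in range(1, 3):
        prev, cur = f"g_{waves[k-1]}", f"g_{waves[k]}"
        ch = f"d_g_{waves[k]}"
        changes.append(ch)
        paths[(prev, cur)] = fixed(1.0)
        paths[(ch, cur)] = fixed(1.0)
        paths[(prev, ch)] = free("beta_g", 0.0)
        _cov(covs, ch, ch, free("zeta_g", design.variance(dA, waves[0]) / 8))
        means[ch] = free("alpha_g", design.mean(dA, waves[k]) - design.mean(dA, waves[k - 1]))
    _cov(covs, changes[0], changes[1], free("psi_g_lag", 0.0))

    variables = (
        [f"{d}_{w}" for d in design.domains for w in waves]
        + [f"{d}_{w}_true" for d in design.domains for w in waves]
        + [f"g_{w}" for w in waves]
        + changes
    )
    observed = tuple(f"{d}_{w}" for d in design.domains for w in waves)
    return ModelSpec("gfactor_lcs", tuple(variables), observed, paths, covs, means)


# ---------------------------------------------------------------------------
# Alternative specifications
# ---------------------------------------------------------------------------


def build_parallel_process(
    design: StudyDesign, *, cross_domain_only: bool = True
) -> ModelSpec:
    """Bivariate latent growth model with cross-domain intercept -> slope paths.

    Each domain has an intercept factor (loadings 1, 1, 1) and a linear
    slope factor (loadings 0, 1, 2 by default); each slope is regressed on
    the *other* domain's intercept — the baseline of one domain driving the
    rate of change of the other.  With ``cross_domain_only=False`` the
    within-domain intercept -> own-slope paths (the "Matthew effect"
    contrast) are freed as well, adding exactly two parameters.
    """
    if design.n_waves < 3:
        raise DesignError("a linear growth model needs at least 3 waves")
    dA, dB = design.domains
    waves = design.wave_labels
    paths: dict = {}
    covs: dict = {}
    means: dict = {}
    _measurement_layer(design, paths, covs)

    for d in design.domains:
        other = dB if d == dA else dA
        icpt, slope = f"int_{d}", f"slope_{d}"
        for w, lam in zip(waves, design.slope_loadings):
            t = f"{d}_{w}_true"
            paths[(icpt, t)] = fixed(1.0)
            paths[(slope, t)] = fixed(lam)
            _cov(covs, t, t, free(f"uresid_{d}_{w}", design.variance(d, w) / 4))
        means[icpt] = free(f"mean_int_{d}", design.mean(d, waves[0]))
        means[slope] = free(
            f"alpha_slope_{d}",
            (design.mean(d, waves[-1]) - design.mean(d, waves[0]))
            / (design.slope_loadings[-1] - design.slope_loadings[0]),
        )
        _cov(covs, icpt, icpt, free(f"var_int_{d}", design.variance(d, waves[0]) / 2))
        _cov(covs, slope, slope, free(f"var_slope_{d}", design.variance(d, waves[0]) / 8))
        cross = f"b_int_{other}_to_slope_{d}"
        paths[(f"int_{other}", slope)] = free(cross, 0.0)
        within = f"b_int_{d}_to_slope_{d}"
        paths[(icpt, slope)] = (
            Param(0.0, within, False) if cross_domain_only else free(within, 0.0)
        )
    _cov(covs, f"int_{dA}", f"int_{dB}", free("cov_int", 0.0))
    _cov(covs, f"slope_{dA}", f"slope_{dB}", free("cov_slope", 0.0))

    variables = (
        [f"{d}_{w}" for d in design.domains for w in waves]
        + [f"{d}_{w}_true" for d in design.domains for w in waves]
        + [f"int_{d}" for d in design.domains]
        + [f"slope_{d}" for d in design.domains]
    )
    observed = tuple(f"{d}_{w}" for d in design.domains for w in waves)
    return ModelSpec(
        "parallel_process" + ("" if cross_domain_only else "_matthew"),
        tuple(variables),
        observed,
        paths,
        covs,
        means,
    )


def build_riclpm(design: StudyDesign) -> ModelSpec:
    """Three-wave random-intercept cross-lagged panel model.

    A per-domain random intercept (unit loadings at every wave) absorbs
    stable between-person differences; the within-person residual
    components carry lag-1 autoregressive and cross-lagged dynamics,
    equated across the two lags by default, with wave-specific residual
    covariances linking the domains.  Observed means are free per variable.
    No reliability layer is used (the within components already absorb
    occasion-specific variance).
    """
    _require_three_waves(design, "RI-CLPM")
    dA, dB = design.domains
    waves = design.wave_labels
    paths: dict = {}
    covs: dict = {}
    means: dict = {}

    for d in design.domains:
        ri = f"ri_{d}"
        _cov(covs, ri, ri, free(f"var_ri_{d}", design.variance(d, waves[0]) / 3))
        for w in waves:
            obs, wv = f"{d}_{w}", f"w_{d}_{w}"
            paths[(ri, obs)] = fixed(1.0)
            paths[(wv, obs)] = fixed(1.0)
            means[obs] = free(f"mean_{d}_{w}", design.mean(d, w))
        w1 = f"w_{d}_{waves[0]}"
        _cov(covs, w1, w1, free(f"var_w_{d}", design.variance(d, waves[0]) / 2))
        other = dB if d == dA else dA
        for k in range(1, 3):
            cur, prev = f"w_{d}_{waves[k]}", f"w_{d}_{waves[k-1]}"
            paths[(prev, cur)] = free(f"ar_{d}", 0.2)
            paths[(f"w_{other}_{waves[k-1]}", cur)] = free(f"cl_{other}_to_{d}", 0.0)
            _cov(covs, cur, cur, free(f"zeta_w_{d}", design.variance(d, waves[k]) / 3))
    _cov(covs, f"ri_{dA}", f"ri_{dB}", free("cov_ri", 0.0))
    _cov(covs, f"w_{dA}_{waves[0]}", f"w_{dB}_{waves[0]}", free("cov_w1", 0.0))
    for w in waves[1:]:
        _cov(covs, f"w_{dA}_{w}", f"w_{dB}_{w}", free(f"psi_w_{w}", 0.0))

    variables = (
        [f"{d}_{w}" for d in design.domains for w in waves]
        + [f"ri_{d}" for d in design.domains]
        + [f"w_{d}_{w}" for d in design.domains for w in waves]
    )
    observed = tuple(f"{d}_{w}" for d in design.domains for w in waves)
    return ModelSpec("riclpm", tuple(variables), observed, paths, covs, means)


# ---------------------------------------------------------------------------
# Constraint editing
# ---------------------------------------------------------------------------


def edit_constraint(
    spec: ModelSpec,
    action: str,
    targets: Sequence[str],
    value: float | None = None,
) -> ModelSpec:
    """Return an edited copy of ``spec``; the original is untouched.

    ``action`` is one of ``free`` (make the labelled parameters free),
    ``fix`` (fix them, optionally to ``value``), or ``equate`` (give them
    all the first target's label, i.e. one shared estimate).
    """
    if action == "free":
        return spec.free_params(targets)
    if action == "fix":
        return spec.fix_params(targets, value)
    if action == "equate":
        if len(targets) < 2:
            raise SemError("equate needs at least two labels")
        return spec.equate_params(targets, targets[0])
    raise SemError(f"unknown edit action {action!r}; use free, fix or equate")
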