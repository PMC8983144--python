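"""Synthetic whole-cell voltage-clamp recordings of KCNQ2/KCNQ3 channels.

The M-current is modelled as a single first-order Hodgkin-Huxley gate: the
steady-state open probability follows a Boltzmann function of voltage,

    p_inf(v) = 1 / (1 + exp((v_half - v) / slope)),

and on a voltage step the gate relaxes exponentially toward p_inf with a
voltage-dependent time constant tau(v).  Whole-cell current is

    I(t) = expr * g_max * p(t) * (v - E_K)            (M-component)
         + g_leak * v                                  (ohmic leak, E_leak = 0)
         + (Cm / Cm_ref) * g_bg * p_bg(t) * (v - E_K)  (endogenous background)
         + white Gaussian noise.

Cohorts emulate automated patch-clamp plates: every cell draws its own
capacitance, seal resistance, series resistance, leak conductance and
expression level, and each cell is recorded twice -- before and after full
XE991 block of the M-component -- so that digital subtraction isolates the
M-current downstream.

Drugs act on the gating parameters: XE991 removes a fraction of the
M-conductance, TEA blocks it with Hill-type concentration dependence, and
retigabine shifts the activation curve hyperpolarized, changes its slope,
scales the conductance and accelerates activation.  The endogenous
background conductance is insensitive to all three, matching its role as
the XE991-resistant component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .protocols import VoltageProtocol, default_protocol
from .records import PRE, POST, CellCovariates, CellRecording

__all__ = [
    "TauParams", "GatingParams", "VariantEffect", "DrugModel",
    "CovariateDistributions", "SimConfig",
    "nernst_potential", "boltzmann", "tau_of_v", "open_probability",
    "apply_drug", "apply_variant", "mix_heterozygous", "simulate_cohort",
    "wt_gating", "background_gating", "default_config",
    "XE991", "TEA", "RETIGABINE",
]

GAS_CONSTANT = 8.314  # J / (mol K)
FARADAY = 96485.0     # C / mol


def nernst_potential(c_out_mM: float = 4.0, c_in_mM: float = 110.0,
                     temperature_K: float = 295.0, valence: int = 1) -> float:
    """Nernst equilibrium potential in mV.

    Defaults reproduce the K+ gradient of the recording solutions
    (4 mM external, 110 mM internal K+ at room temperature), giving
    E_K close to -84 mV.
    """
    if c_out_mM <= 0 or c_in_mM <= 0:
        raise ValueError("ion concentrations must be positive")
    rt_over_zf = GAS_CONSTANT * temperature_K / (valence * FARADAY)
    return 1000.0 * rt_over_zf * math.log(c_out_mM / c_in_mM)


@dataclass(frozen=True)
class TauParams:
    """Sigmoidal voltage dependence of the activation time constant:
    tau(v) = tau_min + tau_amp / (1 + exp((v - v_tau) / k_tau)), in ms."""

    tau_min: float = 60.0
    tau_amp: float = 240.0
    v_tau: float = -30.0
    k_tau: float = 15.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")
        if self.tau_amp < 0:
            raise ValueError("tau_amp must be non-negative")

    def scaled(self, factor: float) -> "TauParams":
        return replace(self, tau_min=self.tau_min * factor,
                       tau_amp=self.tau_amp * factor)


@dataclass(frozen=True)
class GatingParams:
    """Boltzmann activation parameters of one conductance.

    g_max in nS, v_half and slope in mV (slope > 0), e_rev in mV.
    """

    g_max: float
    v_half: float
    slope: float
    tau: TauParams = field(default_factory=TauParams)
    e_rev: float = field(default_factory=nernst_potential)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")


def wt_gating() -> GatingParams:
    """Wild-type KCNQ2/KCNQ3 calibration: V1/2 = -18.9 mV, k = 7.6 mV."""
    return GatingParams(g_max=6.5, v_half=-18.9, slope=7.6)


def boltzmann(v, gating: GatingParams):
    """Steady-state open probability p_inf(v)."""
    return 1.0 / (1.0 + np.exp((gating.v_half - np.asarray(v, float)) / gating.slope))


def tau_of_v(v, tau: TauParams):
    """Activation time constant (ms) at voltage v."""
    v = np.asarray(v, float)
    return tau.tau_min + tau.tau_amp / (1.0 + np.exp((v - tau.v_tau) / tau.k_tau))


def open_probability(v: float, t, gating: GatingParams, v_start: float = -80.0):
    """Open probability at time t (ms) after stepping from v_start to v.

    First-order relaxation p(t) = p_inf(v) + (p0 - p_inf(v)) exp(-t/tau(v)),
    where p0 is the steady state at v_start.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    p_inf = boltzmann(v, gating)
    p0 = boltzmann(v_start, gating)
    return p_inf + (p0 - p_inf) * np.exp(-t / tau_of_v(v, gating.tau))


# ---------------------------------------------------------------------------
# Variant effects and heterozygous mixing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantEffect:
    """Perturbation of WT gating by a channel variant.

    g_scale multiplies the unitary conductance contribution, delta_vhalf
    shifts activation V1/2 (mV), slope_scale and tau_scale multiply the
    slope factor and activation time constant.  dominance in [0, 1]
    controls how strongly a single variant subunit poisons mixed channels:
    0 = additive (haploinsufficiency limit), 1 = fully dominant-negative.
    The identity element (WT) is (1, 0, 1, 1, any).
    """

    g_scale: float = 1.0
    delta_vhalf: float = 0.0
    slope_scale: float = 1.0
    tau_scale: float = 1.0
    dominance: float = 0.0

    def __post_init__(self) -> None:
        if self.g_scale < 0:
            raise ValueError("g_scale must be >= 0")
        if self.slope_scale <= 0 or self.tau_scale <= 0:
            raise ValueError("slope_scale and tau_scale must be positive")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must lie in [0, 1]")


def apply_variant(wt: GatingParams, effect: VariantEffect) -> GatingParams:
    """Gating of a homomeric (variant-only) channel population."""
    return replace(
        wt,
        g_max=wt.g_max * effect.g_scale,
        v_half=wt.v_half + effect.delta_vhalf,
        slope=wt.slope * effect.slope_scale,
        tau=wt.tau.scaled(effect.tau_scale),
    )


def mix_heterozygous(wt: GatingParams, variant: GatingParams,
                     effect: VariantEffect) -> GatingParams:
    """Population-effective gating of a 1:1 WT/variant co-expression.

    Channels carry two KCNQ2 slots (2:2 stoichiometry with KCNQ3) filled
    independently with WT or variant subunits, giving WW/WV/VV classes with
    binomial weights 1/4, 1/2, 1/4.  WW behaves as WT and VV as the
    variant; the mixed WV class has conductance factor
    (1 - d)(1 + s)/2 + d*s (s = g_scale, d = dominance) and gating
    parameters equal to the conductance-weighted mean of WT and variant
    values.  The returned GatingParams is the conductance-weighted
    population average.
    """
    s = effect.g_scale
    d = effect.dominance
    w_mixed = (1.0 - d) * (1.0 + s) / 2.0 + d * s

    # conductance weights of the three channel classes
    weights = np.array([0.25 * 1.0, 0.5 * w_mixed, 0.25 * s])
    g_eff = wt.g_max * float(weights.sum())

    denom = 1.0 + s
    if denom > 0:
        frac_var = s / denom  # variant share within a WV channel
    else:
        frac_var = 0.0

    def wv(attr_wt: float, attr_var: float) -> float:
        return (1.0 - frac_var) * attr_wt + frac_var * attr_var

    vhalf_classes = np.array([wt.v_half, wv(wt.v_half, variant.v_half), variant.v_half])
    slope_classes = np.array([wt.slope, wv(wt.slope, variant.slope), variant.slope])
    taumin_classes = np.array([wt.tau.tau_min, wv(wt.tau.tau_min, variant.tau.tau_min),
                               variant.tau.tau_min])
    tauamp_classes = np.array([wt.tau.tau_amp, wv(wt.tau.tau_amp, variant.tau.tau_amp),
                               variant.tau.tau_amp])

    if weights.sum() > 0:
        w = weights / weights.sum()
        v_half = float(w @ vhalf_classes)
        slope = float(w @ slope_classes)
        tau = replace(wt.tau, tau_min=float(w @ taumin_classes),
                      tau_amp=float(w @ tauamp_classes))
    else:  # fully silent population: parameters are irrelevant
        v_half, slope, tau = wt.v_half, wt.slope, wt.tau

    return replace(wt, g_max=g_eff, v_half=v_half, slope=slope, tau=tau)


# ---------------------------------------------------------------------------
# Drug models
# ---------------------------------------------------------------------------

XE991 = "xe991"
TEA = "tea"
RETIGABINE = "retigabine"


@dataclass(frozen=True)
class DrugModel:
    """Pharmacological transform of M-current gating.

    * xe991: removes ``block_fraction`` of the M-conductance (full block by
      default; concentration is ignored because 25 uM is saturating).
    * tea: Hill-type pore block, g -> g / (1 + (c / ic50)^hill_coeff),
      ic50 in mM (10.7 mM for KCNQ2/KCNQ3 heteromers).
    * retigabine: shifts V1/2 by delta_vhalf_drug, sets the slope factor to
      slope_drug, scales g_max by g_fold and tau by tau_fold, reproducing
      the hyperpolarizing shift (-18.9 -> -47.7 mV) and the 1.4-fold
      current increase at saturating (10 uM) drug.
    """

    kind: str = XE991
    block_fraction: float = 1.0
    ic50: float = 10.7
    hill_coeff: float = 1.0
    delta_vhalf_drug: float = -28.8
    g_fold: float = 1.4
    slope_drug: float = 9.9
    tau_fold: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in (XE991, TEA, RETIGABINE):
            raise ValueError(f"unknown drug kind {self.kind!r}")
        if not 0.0 <= self.block_fraction <= 1.0:
            raise ValueError("block_fraction must lie in [0, 1]")
        if self.ic50 <= 0 or self.hill_coeff <= 0 or self.g_fold <= 0:
            raise ValueError("ic50, hill_coeff and g_fold must be positive")


def apply_drug(gating: GatingParams, drug: DrugModel,
               concentration: float) -> GatingParams:
    """Transform M-component gating under a drug at the given concentration
    (mM for TEA, uM for XE991/retigabine; retigabine and XE991 act as
    on/off at any positive concentration)."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if concentration == 0:
        return gating
    if drug.kind == XE991:
        return replace(gating, g_max=gating.g_max * (1.0 - drug.block_fraction))
    if drug.kind == TEA:
        factor = 1.0 / (1.0 + (concentration / drug.ic50) ** drug.hill_coeff)
        return replace(gating, g_max=gating.g_max * factor)
    if drug.kind == RETIGABINE:
        return replace(
            gating,
            g_max=gating.g_max * drug.g_fold,
            v_half=gating.v_half + drug.delta_vhalf_drug,
            slope=drug.slope_drug,
            tau=gating.tau.scaled(drug.tau_fold),
        )
    raise ValueError(f"unknown drug kind {drug.kind!r}")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormal:
    """Log-normal sampling law parameterized by median and log-space sigma."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))

    @property
    def mean(self) -> float:
        return self.median * math.exp(self.sigma ** 2 / 2.0)

    @property
    def mean_reciprocal(self) -> float:
        return math.exp(self.sigma ** 2 / 2.0) / self.median


def _lognormal_from_cv(mean: float, cv: float) -> LogNormal:
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return LogNormal(median=mean * math.exp(-sigma ** 2 / 2.0), sigma=sigma)


@dataclass(frozen=True)
class CovariateDistributions:
    """Population heterogeneity of per-cell covariates.

    Medians reflect CHO cells on a planar-array chip: ~8 pF capacitance,
    ~1 GOhm seal (with a fifth of cells below the 0.5 GOhm QC cut, so the
    gate is exercised), ~8 MOhm series resistance, ~0.3 nS leak.  The
    expression factor has mean 1 and CV 0.5, emulating electroporation
    variability.
    """

    capacitance: LogNormal = field(default_factory=lambda: LogNormal(8.0, 0.4))
    seal_resistance: LogNormal = field(default_factory=lambda: LogNormal(1.0, 0.8236))
    series_resistance: LogNormal = field(default_factory=lambda: LogNormal(8.0, 0.4))
    leak_conductance: LogNormal = field(default_factory=lambda: LogNormal(0.3, 0.5))
    expression: LogNormal = field(default_factory=lambda: _lognormal_from_cv(1.0, 0.5))

    def sample_cell(self, rng: np.random.Generator,
                    expressing: bool) -> CellCovariates:
        return CellCovariates(
            capacitance=float(self.capacitance.sample(rng, 1)[0]),
            seal_resistance=float(self.seal_resistance.sample(rng, 1)[0]),
            series_resistance=float(self.series_resistance.sample(rng, 1)[0]),
            leak_conductance=float(self.leak_conductance.sample(rng, 1)[0]),
            expression_factor=float(self.expression.sample(rng, 1)[0]) if expressing else 0.0,
        )


def background_gating(wt: GatingParams | None = None,
                      covariates: CovariateDistributions | None = None,
                      contrast_fold: float = 20.0) -> GatingParams:
    """Endogenous XE991-insensitive outward conductance of the host cell.

    Its magnitude is calibrated so that the expected total outward current
    density of a nontransfected cell at +40 mV (background + leak) is
    1/``contrast_fold`` of the expected WT-transfected density, matching
    the observed ~20-fold expression contrast.  The background conductance
    scales with cell capacitance (channel density per membrane area), so
    the calibration uses the covariate population moments.
    """
    wt = wt or wt_gating()
    cov = covariates or CovariateDistributions()
    shape = GatingParams(g_max=1.0, v_half=-10.0, slope=12.0,
                         tau=TauParams(20.0, 50.0, -20.0, 12.0), e_rev=wt.e_rev)
    v = 40.0
    m_density = wt.g_max * float(boltzmann(v, wt)) * (v - wt.e_rev) \
        * cov.capacitance.mean_reciprocal  # E[expr] = 1
    leak_density = v * cov.leak_conductance.mean * cov.capacitance.mean_reciprocal
    bg_density = m_density / (contrast_fold - 1.0) - leak_density
    if bg_density <= 0:
        raise ValueError("contrast_fold too small for the given leak level")
    cm_ref = cov.capacitance.median
    g_bg = bg_density * cm_ref / (float(boltzmann(v, shape)) * (v - shape.e_rev))
    return replace(shape, g_max=g_bg)


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to generate one cohort deterministically."""

    protocol: VoltageProtocol = field(default_factory=default_protocol)
    wt: GatingParams = field(default_factory=wt_gating)
    background: GatingParams | None = None
    covariates: CovariateDistributions = field(default_factory=CovariateDistributions)
    noise_rms: float = 5.0
    n_cells: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")
        if self.background is None:
            object.__setattr__(
                self, "background",
                background_gating(self.wt, self.covariates))


ZYGOSITIES = ("homozygous", "heterozygous", "nontransfected")


def _gate_template(protocol: VoltageProtocol, gating: GatingParams,
                   step_v: float) -> np.ndarray:
    """Open-probability trace over one full sweep (holding/step/tail)."""
    p_hold = float(boltzmann(protocol.holding_potential, gating))
    out = np.empty(protocol.n_samples)
    out[:protocol.n_holding] = p_hold

    t_step = (np.arange(protocol.n_step) + 1) * protocol.sampling_interval
    p_inf = float(boltzmann(step_v, gating))
    tau_s = float(tau_of_v(step_v, gating.tau))
    p_step = p_inf + (p_hold - p_inf) * np.exp(-t_step / tau_s)
    out[protocol.n_holding:protocol.n_holding + protocol.n_step] = p_step

    p_end = p_step[-1] if protocol.n_step else p_hold
    t_tail = (np.arange(protocol.n_tail) + 1) * protocol.sampling_interval
    p_inf_t = float(boltzmann(protocol.tail_voltage, gating))
    tau_t = float(tau_of_v(protocol.tail_voltage, gating.tau))
    out[protocol.n_holding + protocol.n_step:] = \
        p_inf_t + (p_end - p_inf_t) * np.exp(-t_tail / tau_t)
    return out


def _voltage_trace(protocol: VoltageProtocol, step_v: float) -> np.ndarray:
    v = np.empty(protocol.n_samples)
    v[:protocol.n_holding] = protocol.holding_potential
    v[protocol.n_holding:protocol.n_holding + protocol.n_step] = step_v
    v[protocol.n_holding + protocol.n_step:] = protocol.tail_voltage
    return v


def effective_gating(config: SimConfig, effect: VariantEffect | None,
                     zygosity: str,
                     drugs: Sequence[tuple[DrugModel, float]] = ()) -> GatingParams:
    """M-component gating for a group after variant mixing and drugs."""
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"zygosity must be one of {ZYGOSITIES}, got {zygosity!r}")
    wt = config.wt
    if zygosity == "nontransfected":
        gating = replace(wt, g_max=0.0)
    elif zygosity == "homozygous":
        gating = apply_variant(wt, effect or VariantEffect())
    else:
        eff = effect or VariantEffect()
        gating = mix_heterozygous(wt, apply_variant(wt, eff), eff)
    for drug, conc in drugs:
        gating = apply_drug(gating, drug, conc)
    return gating


def _drug_label(drugs: Sequence[tuple[DrugModel, float]]) -> str:
    if not drugs:
        return "none"
    return "+".join(f"{d.kind}:{c:g}" for d, c in drugs)


def simulate_cohort(config: SimConfig, effect: VariantEffect | None = None,
                    zygosity: str = "homozygous",
                    drugs: Sequence[tuple[DrugModel, float]] = (),
                    group: str = "WT", plate: str = "plate0",
                    cell_id_offset: int = 0) -> list[CellRecording]:
    """Simulate a cohort of cells, each recorded pre- and post-XE991.

    Returns a flat list of ``CellRecording`` (two per cell).  Paired
    recordings share covariates; per-cell noise streams are derived from
    the master seed by cell counter, so enlarging a cohort never
    reshuffles earlier cells.
    """
    protocol = config.protocol
    gating = effective_gating(config, effect, zygosity, drugs)
    post_gating = apply_drug(gating, DrugModel(kind=XE991), 25.0)
    bg = config.background
    cm_ref = config.covariates.capacitance.median

    expressing = zygosity != "nontransfected"
    voltages = protocol.step_voltages
    v_traces = {v: _voltage_trace(protocol, v) for v in voltages}
    m_templates = {v: _gate_template(protocol, gating, v) for v in voltages}
    m_templates_post = {v: _gate_template(protocol, post_gating, v) for v in voltages}
    bg_templates = {v: _gate_template(protocol, bg, v) for v in voltages}

    drug_label = _drug_label(drugs)
    recordings: list[CellRecording] = []
    for i in range(config.n_cells):
        idx = cell_id_offset + i
        cell_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,)))
        cov = config.covariates.sample_cell(cell_rng, expressing)
        cell_id = f"{group}_{zygosity}_{drug_label}_{idx:04d}"
        bg_scale = cov.capacitance / cm_ref

        for condition, cond_gating, templates in (
                (PRE, gating, m_templates),
                (POST, post_gating, m_templates_post)):
            sweeps = {}
            for v in voltages:
                vt = v_traces[v]
                i_m = (cov.expression_factor * cond_gating.g_max
                       * templates[v] * (vt - cond_gating.e_rev))
                i_bg = bg_scale * bg.g_max * bg_templates[v] * (vt - bg.e_rev)
                i_leak = cov.leak_conductance * vt
                trace = i_m + i_bg + i_leak
                if config.noise_rms > 0:
                    trace = trace + config.noise_rms * cell_rng.standard_normal(len(vt))
                sweeps[v] = trace
            recordings.append(CellRecording(
                cell_id=cell_id, group=group, zygosity=zygosity,
                drug=drug_label, condition=condition, covariates=cov,
                protocol=protocol, sweeps=sweeps, plate=plate))
    return recordings


def default_config(**overrides) -> SimConfig:
    """Default cohort configuration with the standard WT gating calibration."""
    return SimConfig(**overrides)
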