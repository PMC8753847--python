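"""Synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the animal experiments so every downstream
stage is testable without recordings:

* ``gen_breath_train`` — plethysmograph waveforms whose segmented breaths
  reproduce requested per-breath parameters (Ti, Te, Rt, PIP, PEP, TVi, TVe)
  to sampling tolerance;
* ``gen_fluorometry`` — dual-excitation Fura-2 channel pairs built by
  inverting the Grynkiewicz calibration on a known [Ca2+](t) profile,
  including a post-caffeine undershoot preset;
* ``gen_cohort`` — per-animal tables for a two-group (control / asthma
  model) design, 6 and 9 animals by default, with configurable group
  effects and a latent-severity factor that realises a requested set of
  correlation signs.

All randomness flows from explicit integer seeds; identical configuration
and seed give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .calcium import CalibrationConstants, FluorometryTrace, inverse_grynkiewicz
from .plethysmography import RT_VOLUME_FRACTION

__all__ = [
    "BreathParams",
    "Waveform",
    "CohortConfig",
    "gen_breath_train",
    "gen_fluorometry",
    "gen_cohort",
    "constant_ca_profile",
    "caffeine_undershoot_profile",
    "GUINEA_PIG_BREATH",
    "PAPER_SIGN_MAP",
]


# ---------------------------------------------------------------------------
# breath trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreathParams:
    """Ground-truth parameters of one synthetic breath.

    Durations in seconds, pressures in box-signal units, volumes in ml.
    ``validate=False`` lets tests construct deliberately out-of-range
    breaths (e.g. to exercise the QC filters); the waveform synthesiser
    still requires physical consistency.
    """

    ti: float
    te: float
    rt: float
    pip: float
    pep: float
    tvi: float
    tve: float
    validate: bool = True

    def __post_init__(self) -> None:
        if not self.validate:
            return
        for name in ("ti", "te", "rt", "pip", "pep", "tvi", "tve"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rt > self.te:
            raise ValueError("relaxation time cannot exceed expiratory time")


#: resting guinea-pig breath: ~67 breaths/min, ~2 ml tidal volume
GUINEA_PIG_BREATH = BreathParams(
    ti=0.30, te=0.60, rt=0.25, pip=9.0, pep=8.0, tvi=2.0, tve=2.0
)


@dataclass
class Waveform:
    """Sampled box signal plus the ground truth that produced it."""

    time: np.ndarray
    signal: np.ndarray
    sample_rate: float
    truth: list[dict] = field(default_factory=list)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "signal": self.signal}).to_csv(path, index=False)

    def truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"sample_rate": self.sample_rate, "breaths": self.truth}, fh, indent=1)


def _insp_lobe_exponent(tvi: float, pip: float, ti: float) -> float:
    """Exponent p of the inspiratory lobe PIP * sin(pi t / Ti)^p such that
    the lobe integral equals TVi. Solvable iff 0 < TVi < PIP * Ti."""
    c = tvi / (pip * ti)
    if not 0 < c < 1:
        raise ValueError("infeasible breath: need 0 < TVi < PIP * Ti")

    def integral(p: float) -> float:
        return quad(lambda u: np.sin(np.pi * u) ** p, 0, 1, limit=200)[0]

    return brentq(lambda p: integral(p) - c, 1e-4, 80.0, xtol=1e-10)


def _exp_lobe_params(te: float, rt: float, pep: float, tve: float) -> tuple[float, float]:
    """Expiratory flow shape: mixture of an exponential-decay flow and a
    constant flow, TVe * [(1-w) g(t; tau) + w / Te], chosen so that the peak
    flow equals PEP and the time to expire ``RT_VOLUME_FRACTION`` of TVe
    equals Rt. Returns (tau, w)."""
    if not 0 < rt < RT_VOLUME_FRACTION * te:
        raise ValueError(
            f"infeasible breath: need 0 < Rt < {RT_VOLUME_FRACTION} * Te for the "
            "exponential-mixture expiratory lobe"
        )

    def cdf_exp(t: float, tau: float) -> float:
        return (1 - np.exp(-t / tau)) / (1 - np.exp(-te / tau))

    def w_of_tau(tau: float) -> float:
        e = cdf_exp(rt, tau)
        return (RT_VOLUME_FRACTION - e) / (rt / te - e)

    def peak_flow(tau: float) -> float:
        w = w_of_tau(tau)
        g0 = (1 / tau) / (1 - np.exp(-te / tau))
        return tve * ((1 - w) * g0 + w / te)

    # tau* where the pure exponential already places Rt correctly (w = 0);
    # shrinking tau raises the peak flow without bound
    tau_star = brentq(lambda tau: cdf_exp(rt, tau) - RT_VOLUME_FRACTION, 1e-6 * te, 1e3 * te, xtol=1e-12)
    if pep <= peak_flow(tau_star):
        raise ValueError("infeasible breath: PEP below the minimum achievable peak expiratory flow")
    tau = brentq(lambda tau: peak_flow(tau) - pep, 1e-6 * te, tau_star, xtol=1e-14)
    return tau, w_of_tau(tau)


def synth_breath(params: BreathParams, sample_rate: float) -> np.ndarray:
    """One breath as samples of a flow-like signal (inspiration positive)."""
    p = _insp_lobe_exponent(params.tvi, params.pip, params.ti)
    tau, w = _exp_lobe_params(params.te, params.rt, params.pep, params.tve)
    n_i = int(round(params.ti * sample_rate))
    n_e = int(round(params.te * sample_rate))
    t_i = np.arange(n_i) / sample_rate
    t_e = np.arange(n_e) / sample_rate
    insp = params.pip * np.sin(np.pi * t_i / params.ti) ** p
    g = (np.exp(-t_e / tau) / tau) / (1 - np.exp(-params.te / tau))
    exp_flow = params.tve * ((1 - w) * g + w / params.te)
    return np.concatenate([insp, -exp_flow])


def gen_breath_train(
    params_sequence: list[BreathParams],
    sample_rate: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Waveform:
    """Concatenate synthetic breaths into a sampled waveform.

    Each breath's segmented features reproduce its ``BreathParams`` to
    sampling tolerance; ``truth`` records onset time and parameters per
    breath. An empty parameter list yields an empty waveform.
    """
    if sample_rate < 50:
        raise ValueError("sample_rate must be at least 50 Hz")
    rng = np.random.default_rng(seed)
    chunks, truth = [], []
    t0 = 0.0
    for p in params_sequence:
        x = synth_breath(p, sample_rate)
        truth.append(
            {"onset_s": t0, "ti": p.ti, "te": p.te, "rt": p.rt, "pip": p.pip,
             "pep": p.pep, "tvi": p.tvi, "tve": p.tve}
        )
        chunks.append(x)
        t0 += x.size / sample_rate
    signal = np.concatenate(chunks) if chunks else np.array([])
    if noise_sd > 0 and signal.size:
        signal = signal + rng.normal(0, noise_sd, signal.size)
    time = np.arange(signal.size) / sample_rate
    return Waveform(time=time, signal=signal, sample_rate=sample_rate, truth=truth)


# ---------------------------------------------------------------------------
# fluorometry
# ---------------------------------------------------------------------------

def constant_ca_profile(level_nm: float, duration_s: float, dt: float = 0.5):
    """(time, Ca) arrays for a steady concentration."""
    t = np.arange(0.0, duration_s, dt)
    return t, np.full(t.size, float(level_nm))


def caffeine_undershoot_profile(
    basal_nm: float = 137.0,
    decline_rate: float = 4.6,
    caffeine_on: float = 30.0,
    caffeine_duration: float = 120.0,
    peak_nm: float = 600.0,
    plateau_delta: float = 80.0,
    undershoot_depth: float = 40.0,
    recovery_tau: float = 40.0,
    duration_s: float = 280.0,
    dt: float = 0.5,
):
    """[Ca2+](t) for a caffeine SR-depletion / refilling experiment.

    Basal level until ``caffeine_on``; a caffeine transient (sharp peak
    relaxing to a plateau ``plateau_delta`` above basal); at withdrawal a
    linear decline at ``decline_rate`` nM/s that crosses basal and bottoms
    out ``undershoot_depth`` below it (the SR-refilling undershoot), then an
    exponential recovery to basal. Returns (time, ca, withdrawal_time).
    """
    t = np.arange(0.0, duration_s, dt)
    ca = np.full(t.size, float(basal_nm))
    withdrawal = caffeine_on + caffeine_duration
    plateau = basal_nm + plateau_delta
    in_caff = (t >= caffeine_on) & (t < withdrawal)
    ca[in_caff] = plateau + (peak_nm - plateau) * np.exp(-(t[in_caff] - caffeine_on) / 3.0)
    t_min = withdrawal + (plateau - (basal_nm - undershoot_depth)) / decline_rate
    decline = (t >= withdrawal) & (t <= t_min)
    ca[decline] = plateau - decline_rate * (t[decline] - withdrawal)
    rec = t > t_min
    ca[rec] = basal_nm - undershoot_depth * np.exp(-(t[rec] - t_min) / recovery_tau)
    return t, ca, withdrawal


def gen_fluorometry(
    time,
    true_ca,
    constants: CalibrationConstants = CalibrationConstants(),
    noise_sd: float = 0.005,
    seed: int = 0,
    f380_net: float = 500.0,
    b340: float = 50.0,
    b380: float = 50.0,
) -> FluorometryTrace:
    """Dual-channel fluorescence whose ratio encodes ``true_ca``.

    The noise model perturbs the 340/380 ratio directly (Gaussian,
    ``noise_sd`` in ratio units, default 0.005); channels are then
    reconstructed around a constant net 380 signal so the forward pipeline
    (background subtraction, ratio, Grynkiewicz) recovers the profile.
    """
    time = np.asarray(time, dtype=float)
    true_ca = np.asarray(true_ca, dtype=float)
    if np.any(true_ca < 0):
        raise ValueError("Ca2+ concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    r = inverse_grynkiewicz(true_ca, constants)
    if noise_sd > 0:
        r = r + rng.normal(0, noise_sd, r.size)
    f380 = np.full(time.size, f380_net + b380)
    f340 = r * f380_net + b340
    return FluorometryTrace(
        time=time, f340=f340, f380=f380, b340=b340, b380=b380,
        meta={"true_ca": true_ca, "constants": constants, "noise_sd": noise_sd, "seed": seed},
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

#: correlation signs the analysis is expected to detect in a default cohort
PAPER_SIGN_MAP: dict[tuple[str, str], int] = {
    ("gsh", "rmax"): -1,
    ("gsh", "pd200_ratio"): +1,
    ("pct_tgfb1", "rmax"): +1,
    ("pct_serca2b", "dbaseline_bi"): -1,
    ("pct_serca2b", "pct_il13"): +1,
}

#: control-group means in each variable's reported units
CONTROL_MEANS: dict[str, float] = {
    "rmax": 2.0,            # Bi units
    "pd200_ratio": 1.0,
    "dbaseline_bi": 0.0,    # Bi units
    "gsh": 4.0,             # ELISA units (arbitrary)
    "pct_tgfb1": 10.0,      # % positive myocytes
    "pct_il13": 15.0,
    "pct_serca2b": 40.0,
    "ca_basal": 137.0,      # nM
    "undershoot_rate": 4.6, # nM/s
    "baseline_bi": 0.8,     # Bi units, pre-provocation intrinsic tone
}

#: asthma-minus-control group shifts (same units as the variable)
DEFAULT_EFFECTS: dict[str, float] = {
    "rmax": 6.0,
    "pd200_ratio": -0.6,
    "dbaseline_bi": 1.5,
    "gsh": -1.5,
    "pct_tgfb1": 15.0,
    "pct_il13": 0.0,
    "pct_serca2b": 0.0,
    "ca_basal": 2.0,
    "undershoot_rate": -0.3,
    "baseline_bi": 0.2,
}

DEFAULT_NOISE: dict[str, float] = {
    "rmax": 1.5,
    "pd200_ratio": 0.2,
    "dbaseline_bi": 0.5,
    "gsh": 0.8,
    "pct_tgfb1": 5.0,
    "pct_il13": 5.0,
    "pct_serca2b": 8.0,
    "ca_basal": 15.0,
    "undershoot_rate": 1.0,
    "baseline_bi": 0.15,
}

#: variables bounded below at ~0 in their natural units
_NONNEG = ("rmax", "pd200_ratio", "gsh", "pct_tgfb1", "pct_il13", "pct_serca2b",
           "ca_basal", "undershoot_rate", "baseline_bi")


@dataclass
class CohortConfig:
    """Two-group cohort design.

    ``effects`` maps variable -> asthma-minus-control mean shift; ``signs``
    maps unordered variable pairs -> required correlation sign, realised by
    a shared latent severity factor with signed loadings;
    ``latent_strength`` is the loading as a fraction of each variable's
    noise scale. The study design is 6 control and 9 asthma-model animals.
    """

    n_control: int = 6
    n_asthma: int = 9
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    signs: dict = field(default_factory=lambda: dict(PAPER_SIGN_MAP))
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    latent_strength: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_asthma < 2:
            raise ValueError("need at least 2 animals per group")
        if not 0 <= self.latent_strength < 1:
            raise ValueError("latent_strength must lie in [0, 1)")


def _solve_sign_assignment(signs: dict, effects: dict) -> dict[str, int]:
    """Assign each variable a sign so that products match the sign map.

    Signed-graph balance via union-find with parity; an unsatisfiable
    (frustrated-cycle) map raises ValueError. Components are oriented so
    the latent factor agrees with the first non-zero group effect found in
    the component, making pooled-cohort correlations reinforce, not fight,
    the group structure.
    """
    parent: dict[str, str] = {}
    parity: dict[str, int] = {}  # sign relative to component root (+1/-1)

    def find(v: str) -> tuple[str, int]:
        if parent[v] == v:
            return v, 1
        root, sgn = find(parent[v])
        parent[v], parity[v] = root, sgn * parity[v]
        return root, parity[v]

    for (a, b), s in signs.items():
        if s not in (-1, 1):
            raise ValueError("sign map values must be +1 or -1")
        for v in (a, b):
            parent.setdefault(v, v)
            parity.setdefault(v, 1)
        ra, sa = find(a)
        rb, sb = find(b)
        if ra == rb:
            if sa * sb != s:
                raise ValueError(f"contradictory sign map: cycle through ({a}, {b}) is frustrated")
        else:
            parent[rb] = ra
            parity[rb] = s * sa * sb

    out: dict[str, int] = {}
    orient: dict[str, int] = {}
    for v in parent:
        root, sgn = find(v)
        out[v] = sgn
    for v in sorted(parent, key=lambda v: (find(v)[0], v)):
        root, _ = find(v)
        if root not in orient and effects.get(v, 0.0) != 0.0:
            orient[root] = 1 if (effects[v] > 0) == (out[v] > 0) else -1
    for v in out:
        out[v] *= orient.get(find(v)[0], 1)
    return out


def gen_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """One row per animal: group label, functional outcomes, phenotype panel.

    Each variable is control_mean + group_effect + loading * f + noise,
    where f ~ N(0,1) is a per-animal latent severity factor shared across
    variables, loadings carry the signs solved from ``config.signs``, and
    the residual noise is scaled so the total variance matches
    ``config.noise``. Also emits raw flow-cytometry counts (10,000 gated
    events per marker) and qPCR Ct pairs consistent with the percentage and
    expression columns, plus a three-challenge Bi series for the
    repeated-measures analysis. Fully determined by ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    var_signs = _solve_sign_assignment(cfg.signs, cfg.effects)
    n = cfg.n_control + cfg.n_asthma
    group = np.array(["control"] * cfg.n_control + ["asthma"] * cfg.n_asthma)
    is_asthma = (group == "asthma").astype(float)
    f = rng.normal(0, 1, n)

    df = pd.DataFrame({"animal_id": [f"gp{i + 1:02d}" for i in range(n)], "group": group})
    lam = cfg.latent_strength
    for var in CONTROL_MEANS:
        sd = cfg.noise[var]
        sigma_load = var_signs.get(var, 0) * lam * sd
        resid = sd * np.sqrt(1 - lam**2) if var in var_signs else sd
        vals = (
            CONTROL_MEANS[var]
            + cfg.effects.get(var, 0.0) * is_asthma
            + sigma_load * f
            + rng.normal(0, resid, n)
        )
        if var in _NONNEG:
            vals = np.clip(vals, 1e-6, None)
        if var.startswith("pct_"):
            vals = np.clip(vals, 0.0, 100.0)
        df[var] = vals

    # PD200 doses consistent with the ratio (pre drawn, post = pre * ratio)
    df["pd200_pre"] = np.exp(rng.normal(np.log(0.03), 0.3, n))
    df["pd200_post"] = df["pd200_pre"] * df["pd200_ratio"]

    # raw flow counts at 10,000 gated events per marker, isotype 0.6%
    isotype = 0.6
    for marker in ("tgfb1", "il13", "serca2b"):
        total = 10_000
        pos = np.round((df[f"pct_{marker}"] + isotype) / 100.0 * total).astype(int)
        df[f"events_total_{marker}"] = total
        df[f"events_pos_{marker}"] = np.clip(pos, 0, total)
        df[f"isotype_pct_{marker}"] = isotype

    # qPCR: SERCA2B relative expression 2^-dCt, lower in the asthma model
    log2_expr = rng.normal(-10.0, 0.4, n) - 2.0 * is_asthma
    df["ct_18s"] = rng.normal(10.0, 0.2, n)
    df["ct_serca2b"] = df["ct_18s"] - log2_expr
    df["serca2b_expr"] = 2.0 ** log2_expr

    # per-challenge maximal obstruction for the repeated-measures stage
    for k, scale in enumerate((0.8, 0.9, 1.0), start=1):
        df[f"bi_challenge_{k}"] = np.clip(
            df["baseline_bi"]
            + scale * (df["rmax"] - CONTROL_MEANS["rmax"] + 1.0)
            + rng.normal(0, 0.3, n),
            1e-6,
            None,
        )
    return df
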