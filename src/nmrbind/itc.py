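"""ITC binding-isotherm simulation and fitting.

Forward-simulates and fits isothermal titration calorimetry data for the
single-site (Wiseman) model and the sequential-sites model.  The cell
contains the macromolecule at ``cell_conc``; the syringe titrates ligand in
small injections.  Each injection displaces cell volume, so both the
macromolecule and the already-injected ligand are diluted by the standard
per-injection factor (1 - dV/V0) — the same convention is used by the
simulator and the fitter, which matters more than which convention is
chosen.

Heats are expressed per mole of injectant (kcal/mol), the scale on which
instruments plot binding isotherms.  Derived thermodynamics use
R = 1.9872 cal/(mol K):

    Kd [uM] = 1e6 / Ka [1/M]
    dG = -R*T*ln(Ka)          [kcal/mol]
    dS = 1000*(dH - dG)/T     [cal/(mol K)]
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

R_CAL = 1.9872  # cal/(mol K)


@dataclass
class TitrationScheme:
    """Instrument and sample layout for one titration experiment."""

    cell_volume: float = 200.0        # uL
    cell_conc: float = 100.0          # uM macromolecule in the cell
    syringe_conc: float = 1000.0      # uM titrant in the syringe
    injection_volumes: tuple[float, ...] = (2.0,) * 20  # uL each
    spacing_s: float = 150.0          # metadata only
    temperature: float = 298.0        # K

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_conc, self.syringe_conc,
               self.temperature) <= 0:
            raise ValueError("cell volume, concentrations and temperature must be > 0")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be > 0")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Post-injection total concentrations (M_i, X_i) in uM.

        Both species are diluted by (1 - dV_i/V0) at each injection; the
        injected ligand adds syringe_conc * dV_i/V0.
        """
        M = np.empty(self.n_injections)
        X = np.empty(self.n_injections)
        m, x = self.cell_conc, 0.0
        for i, dv in enumerate(self.injection_volumes):
            f = 1.0 - dv / self.cell_volume
            m *= f
            x = x * f + self.syringe_conc * dv / self.cell_volume
            M[i], X[i] = m, x
        return M, X


@dataclass
class Isotherm:
    """Integrated injection heats in kcal per mole of injectant."""

    heats: np.ndarray                 # kcal/mol injectant, one per injection
    molar_ratio: np.ndarray           # cumulative X_i / M_i (dilution-corrected)
    raw_heats: np.ndarray | None = None  # ucal, optional

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if self.heats.shape != self.molar_ratio.shape:
            raise ValueError("heats and molar_ratio must have equal length")

    def __len__(self) -> int:
        return len(self.heats)


@dataclass
class BindingParams:
    """Single-site binding parameters and thermodynamic derivations."""

    N: float                          # stoichiometry (sites per macromolecule)
    Ka: float                         # 1/M
    dH: float                         # kcal/mol
    temperature: float = 298.0        # K
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.Ka <= 0:
            raise ValueError("Ka must be positive")

    @property
    def Kd_uM(self) -> float:
        return 1e6 / self.Ka

    @property
    def dG(self) -> float:
        """kcal/mol, from dG = -RT ln Ka."""
        return -R_CAL * 1e-3 * self.temperature * math.log(self.Ka)

    @property
    def dS(self) -> float:
        """cal/(mol K), from dS = 1000 (dH - dG)/T."""
        return 1000.0 * (self.dH - self.dG) / self.temperature

    @classmethod
    def from_kd_um(cls, N: float, dH: float, kd_um: float,
                   temperature: float = 298.0) -> "BindingParams":
        return cls(N=N, Ka=1e6 / kd_um, dH=dH, temperature=temperature)


@dataclass
class SequentialParams:
    """Stepwise sequential-sites parameters: site i binds after site i-1."""

    Ka: tuple[float, ...]             # 1/M, stepwise macroscopic constants
    dH: tuple[float, ...]             # kcal/mol per step
    temperature: float = 298.0
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.Ka) != len(self.dH):
            raise ValueError("Ka and dH must have one entry per site")
        if any(k <= 0 for k in self.Ka):
            raise ValueError("all Ka must be positive")

    @property
    def k(self) -> int:
        return len(self.Ka)


# ---------------------------------------------------------------------------
# Forward models

def _cumulative_heats_one_site(params: BindingParams,
                               scheme: TitrationScheme) -> np.ndarray:
    """Cumulative cell heat content Q_i (kcal) after each injection.

    theta solves the single-site mass-action quadratic at post-injection
    total concentrations; Q = N*theta*M*V0*dH.
    """
    M, X = scheme.concentrations()           # uM
    M_m, X_m = M * 1e-6, X * 1e-6            # mol/L
    Ka = params.Ka
    nM = params.N * M_m
    # theta^2 - theta*(1 + X/(N M) + 1/(N M Ka)) + X/(N M) = 0
    b = 1.0 + X_m / nM + 1.0 / (nM * Ka)
    c = X_m / nM
    theta = (b - np.sqrt(b * b - 4.0 * c)) / 2.0
    V0_L = scheme.cell_volume * 1e-6
    # moles bound * dH[kcal/mol] * 1e3 -> heat in cal
    return params.N * theta * M_m * V0_L * params.dH * 1e3


def _per_injection_heats(Q: np.ndarray, scheme: TitrationScheme) -> np.ndarray:
    """Per-injection heats dQ_i from cumulative Q, with displaced-volume
    correction dQ_i = Q_i - Q_{i-1} + (dV_i/V0)*(Q_i + Q_{i-1})/2."""
    dV = np.asarray(scheme.injection_volumes)
    Q_prev = np.concatenate([[0.0], Q[:-1]])
    return Q - Q_prev + (dV / scheme.cell_volume) * (Q + Q_prev) / 2.0


def _heats_per_mole(dQ: np.ndarray, scheme: TitrationScheme) -> np.ndarray:
    """Normalize injection heats by moles of injectant per injection."""
    dV_L = np.asarray(scheme.injection_volumes) * 1e-6
    moles = scheme.syringe_conc * 1e-6 * dV_L
    return dQ * 1e-3 / moles  # cal -> kcal


def one_site_curve(params: BindingParams, scheme: TitrationScheme) -> np.ndarray:
    """Noise-free Wiseman isotherm: kcal per mole of injectant per injection."""
    Q = _cumulative_heats_one_site(params, scheme)
    return _heats_per_mole(_per_injection_heats(Q, scheme), scheme)


def molar_ratios(scheme: TitrationScheme) -> np.ndarray:
    M, X = scheme.concentrations()
    return X / M


def simulate_one_site(
    params: BindingParams,
    scheme: TitrationScheme,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Simulate a one-site isotherm with additive Gaussian heat noise.

    Noise (SD in kcal/mol of injectant) is added per point; the result is
    bit-reproducible given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = one_site_curve(params, scheme)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Isotherm(heats=heats, molar_ratio=molar_ratios(scheme))


def sequential_curve(params: SequentialParams,
                     scheme: TitrationScheme) -> np.ndarray:
    """Noise-free sequential-sites isotherm (kcal/mol injectant).

    Species with j ligands bound have population proportional to
    beta_j * [X]^j with beta_j the product of stepwise constants; the free
    ligand concentration solves the mass balance by bracketed root-finding.
    """
    M, X = scheme.concentrations()
    M_m, X_m = M * 1e-6, X * 1e-6
    beta = np.cumprod(params.Ka)                     # beta_j, j = 1..k
    cum_dH = np.cumsum(params.dH)                    # enthalpy of j-bound state
    k = params.k
    Q = np.empty(len(M_m))
    V0_L = scheme.cell_volume * 1e-6
    for i in range(len(M_m)):
        Mt, Xt = M_m[i], X_m[i]

        def balance(x_free: float) -> float:
            pj = beta * x_free ** np.arange(1, k + 1)
            P = 1.0 + pj.sum()
            nbar = (np.arange(1, k + 1) * pj).sum() / P
            return x_free + Mt * nbar - Xt

        x = brentq(balance, 0.0, Xt) if Xt > 0 else 0.0
        pj = beta * x ** np.arange(1, k + 1)
        P = 1.0 + pj.sum()
        frac = pj / P
        Q[i] = Mt * V0_L * float((frac * cum_dH).sum()) * 1e3  # cal
    return _heats_per_mole(_per_injection_heats(Q, scheme), scheme)


def simulate_sequential(
    params: SequentialParams,
    scheme: TitrationScheme,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = sequential_curve(params, scheme)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Isotherm(heats=heats, molar_ratio=molar_ratios(scheme))


# ---------------------------------------------------------------------------
# Isotherm I/O

def isotherm_to_tsv(isotherm: Isotherm, scheme: TitrationScheme, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "injection": np.arange(1, len(isotherm) + 1),
        "volume_uL": scheme.injection_volumes,
        "molar_ratio": isotherm.molar_ratio,
        "heat_kcal_per_mol": isotherm.heats,
    }).to_csv(path, sep="\t", index=False, float_format="%.6f")


def isotherm_from_tsv(path) -> Isotherm:
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+", comment="#")
    return Isotherm(
        heats=df["heat_kcal_per_mol"].to_numpy(),
        molar_ratio=df["molar_ratio"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Dilution control

def subtract_dilution(sample: Isotherm, control: Isotherm) -> Isotherm:
    """Subtract a buffer-titration (heat of dilution) control pointwise."""
    if len(sample) != len(control):
        raise ValueError(
            f"injection count mismatch: sample {len(sample)}, control {len(control)}"
        )
    return Isotherm(
        heats=sample.heats - control.heats,
        molar_ratio=sample.molar_ratio.copy(),
    )


# ---------------------------------------------------------------------------
# Fitting

def _initial_guess(isotherm: Isotherm, scheme: TitrationScheme) -> BindingParams:
    """Heuristic start: N from the inflection of the sigmoid, dH from the
    first-plateau mean, Ka from the slope at the inflection."""
    heats = isotherm.heats
    ratio = isotherm.molar_ratio
    n_head = max(2, len(heats) // 5)
    dH0 = float(np.mean(heats[:n_head]))
    if abs(dH0) < 1e-12:
        dH0 = float(heats[np.argmax(np.abs(heats))]) or -1.0
    # inflection ~ steepest descent of |heat| vs ratio
    d = np.diff(heats) / np.maximum(np.diff(ratio), 1e-12)
    i_inf = int(np.argmax(np.abs(d))) + 1
    N0 = float(np.clip(ratio[i_inf], 0.1, 10.0))
    slope = abs(d[i_inf - 1] / dH0) if dH0 else 1.0
    Ka0 = float(np.clip(slope / (scheme.cell_conc * 1e-6), 1e2, 1e9))
    return BindingParams(N=N0, Ka=Ka0, dH=dH0, temperature=scheme.temperature)


def fit_one_site(
    isotherm: Isotherm,
    scheme: TitrationScheme,
    init: BindingParams | None = None,
    weights: np.ndarray | None = None,
    discard_first: bool = False,
) -> BindingParams:
    """Weighted least-squares fit of the one-site Wiseman model.

    Fits (N, log10 Ka, dH) against the same forward model as the simulator.
    Non-convergence is flagged on the result, not raised; a c-value
    (N * cell_conc * Ka) below 1 triggers a warning that N is poorly
    determined.  Parameter standard errors come from the Jacobian at the
    optimum.
    """
    if len(isotherm) < 6:
        raise ValueError("need at least 6 injections to fit a one-site model")
    mask = np.ones(len(isotherm), dtype=bool)
    if discard_first:
        mask[0] = False
    y = isotherm.heats[mask]
    w = np.ones_like(y) if weights is None else np.asarray(weights)[mask]

    p0 = init if init is not None else _initial_guess(isotherm, scheme)

    def residuals(x: np.ndarray) -> np.ndarray:
        N, logKa, dH = x
        model = one_site_curve(
            BindingParams(N=N, Ka=10.0 ** logKa, dH=dH,
                          temperature=scheme.temperature),
            scheme,
        )
        return (model[mask] - y) * w

    x0 = np.array([p0.N, math.log10(p0.Ka), p0.dH])
    sol = least_squares(
        residuals, x0,
        bounds=([1e-3, 1.0, -1e3], [1e2, 12.0, 1e3]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    N, logKa, dH = sol.x
    se = _standard_errors(sol, names=("N", "logKa", "dH"))
    params = BindingParams(
        N=float(N), Ka=float(10.0 ** logKa), dH=float(dH),
        temperature=scheme.temperature, se=se, converged=bool(sol.success),
    )
    if not sol.success:
        warnings.warn("one-site fit did not converge; result flagged")
    c_value = params.N * scheme.cell_conc * 1e-6 * params.Ka
    if c_value < 1.0:
        warnings.warn(
            f"c-value {c_value:.2g} < 1: stoichiometry N poorly determined"
        )
    return params


def fit_sequential(
    isotherm: Isotherm,
    scheme: TitrationScheme,
    k: int,
    init: SequentialParams | None = None,
) -> SequentialParams:
    """Least-squares fit of the stepwise sequential-sites model (k sites).

    k = 1 reduces exactly to the one-site model with N fixed at 1.
    Under-determined fits are flagged through large parameter standard
    errors rather than refused.
    """
    if k < 1 or k > 3:
        raise ValueError("k must be 1, 2 or 3")
    y = isotherm.heats

    if init is None:
        base = _initial_guess(isotherm, scheme)
        Ka0 = tuple(base.Ka * (0.5 ** i) for i in range(k))
        dH0 = tuple(base.dH for _ in range(k))
        init = SequentialParams(Ka=Ka0, dH=dH0, temperature=scheme.temperature)

    def unpack(x: np.ndarray) -> SequentialParams:
        return SequentialParams(
            Ka=tuple(10.0 ** v for v in x[:k]),
            dH=tuple(x[k:]),
            temperature=scheme.temperature,
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        return sequential_curve(unpack(x), scheme) - y

    x0 = np.concatenate([np.log10(init.Ka), init.dH])
    sol = least_squares(
        residuals, x0,
        bounds=(np.concatenate([np.full(k, 1.0), np.full(k, -1e3)]),
                np.concatenate([np.full(k, 12.0), np.full(k, 1e3)])),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    names = tuple(f"logKa{i+1}" for i in range(k)) + tuple(
        f"dH{i+1}" for i in range(k))
    se = _standard_errors(sol, names=names)
    out = unpack(sol.x)
    out.se.update(se)
    out.converged = bool(sol.success)
    if not sol.success:
        warnings.warn("sequential fit did not converge; result flagged")
    return out


def _standard_errors(sol, names: tuple[str, ...]) -> dict[str, float]:
    """Asymptotic SEs from the least-squares Jacobian (NaN if singular)."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        errs = np.full(n, np.nan)
    return dict(zip(names, errs.tolist()))
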