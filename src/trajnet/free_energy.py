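"""Binding thermodynamics and alchemical free-energy estimators.

Two layers live here:

1. Cycle bookkeeping — conversion of inhibition constants to binding free
   energies (ΔG = −RT ln Ki, 1 M standard state) and the double
   thermodynamic cycle that yields the relative free-energy change ΔΔG
   together with its closure residual.

2. Estimators over potential-energy-difference samples — exponential
   averaging (Zwanzig), the two-state Bennett acceptance ratio (BAR) and
   its multistate generalisation (MBAR), plus window stitching.

Units: energies in kcal/mol, temperatures in K, Ki in nM unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .errors import ConvergenceError, SpecError

__all__ = [
    "R_KCAL",
    "BindingAffinity",
    "ThermoCycle",
    "CycleResult",
    "FEPWindow",
    "FEPSamples",
    "ki_to_dg",
    "dg_to_ki",
    "cycle_ddg",
    "zwanzig",
    "bar",
    "mbar",
    "stitch_windows",
    "estimate_fep",
    "read_fep_table",
    "write_fep_table",
]

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.98720425e-3


# ---------------------------------------------------------------------------
# Ki <-> ΔG and thermodynamic cycle
# ---------------------------------------------------------------------------

def ki_to_dg(ki_nm: float, temperature: float = 300.0) -> float:
    """Binding free energy from an inhibition constant.

    ΔG = RT ln(Ki / 1 M) with Ki supplied in nM and a 1 M standard state
    (equivalently −RT ln of the association constant), so nanomolar
    inhibitors yield large negative binding free energies. Strictly
    increasing in Ki: tighter binding is more negative.
    """
    if ki_nm <= 0:
        raise SpecError(f"Ki must be positive, got {ki_nm}")
    if temperature <= 0:
        raise SpecError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature * math.log(ki_nm * 1e-9)


def dg_to_ki(dg: float, temperature: float = 300.0) -> float:
    """Inverse of :func:`ki_to_dg`; returns Ki in nM."""
    if temperature <= 0:
        raise SpecError(f"temperature must be positive, got {temperature}")
    return math.exp(dg / (R_KCAL * temperature)) * 1e9


@dataclass(frozen=True)
class BindingAffinity:
    """An experimental Ki measurement and its derived binding free energy."""

    protein: str
    ligand: str
    ki_nm: float
    ki_err_nm: float = 0.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.ki_nm <= 0:
            raise SpecError(f"Ki must be positive, got {self.ki_nm}")

    @property
    def dg(self) -> float:
        return ki_to_dg(self.ki_nm, self.temperature)

    @property
    def dg_err(self) -> float:
        """First-order propagation: δΔG = RT·δKi/Ki."""
        return R_KCAL * self.temperature * self.ki_err_nm / self.ki_nm


@dataclass
class ThermoCycle:
    """Double thermodynamic cycle over two proteins and two ligands.

    ``binding`` maps (protein, ligand) to (ΔG_bind, error); ``alchemical``
    maps protein to (ΔG_ligA→ligB, error) for the ligand transformation.
    """

    proteins: tuple[str, str]  # (reference, variant)
    ligands: tuple[str, str]   # (ligand A, ligand B)
    binding: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    alchemical: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class CycleResult:
    ddg_experimental: float
    ddg_experimental_err: float
    ddg_alchemical: float
    ddg_alchemical_err: float
    closure: float
    closure_err: float


def cycle_ddg(cycle: ThermoCycle) -> CycleResult:
    """Relative free-energy change from the double cycle.

    ΔΔG_exp = (ΔG_bind,A^variant − ΔG_bind,A^ref)
            − (ΔG_bind,B^variant − ΔG_bind,B^ref)
    ΔΔG_alch = ΔG_A→B^ref − ΔG_A→B^variant
    closure  = ΔΔG_exp − ΔΔG_alch

    Errors combine in quadrature (independent edges).
    """
    ref, var = cycle.proteins
    lig_a, lig_b = cycle.ligands
    edges = [(var, lig_a), (ref, lig_a), (var, lig_b), (ref, lig_b)]
    for e in edges:
        if e not in cycle.binding:
            raise SpecError(f"missing binding edge {e!r} in thermodynamic cycle")
    for p in (ref, var):
        if p not in cycle.alchemical:
            raise SpecError(f"missing alchemical edge {p!r} in thermodynamic cycle")

    (g_va, e_va), (g_ra, e_ra) = cycle.binding[edges[0]], cycle.binding[edges[1]]
    (g_vb, e_vb), (g_rb, e_rb) = cycle.binding[edges[2]], cycle.binding[edges[3]]
    ddg_exp = (g_va - g_ra) - (g_vb - g_rb)
    ddg_exp_err = math.sqrt(e_va**2 + e_ra**2 + e_vb**2 + e_rb**2)

    (a_ref, ae_ref) = cycle.alchemical[ref]
    (a_var, ae_var) = cycle.alchemical[var]
    ddg_alch = a_ref - a_var
    ddg_alch_err = math.sqrt(ae_ref**2 + ae_var**2)

    closure = ddg_exp - ddg_alch
    closure_err = math.sqrt(ddg_exp_err**2 + ddg_alch_err**2)
    return CycleResult(ddg_exp, ddg_exp_err, ddg_alch, ddg_alch_err,
                       closure, closure_err)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def zwanzig(delta_u: np.ndarray, temperature: float = 300.0) -> float:
    """Exponential-average (free energy perturbation) estimate.

    ΔF = −RT ln⟨exp(−ΔU/RT)⟩, evaluated with log-sum-exp so that very
    negative ΔU samples cannot overflow.
    """
    du = np.asarray(delta_u, dtype=float)
    if du.size == 0:
        raise SpecError("zwanzig requires at least one sample")
    rt = R_KCAL * temperature
    return -rt * (logsumexp(-du / rt) - math.log(du.size))


def bar(
    forward: np.ndarray,
    backward: np.ndarray,
    temperature: float = 300.0,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Bennett acceptance ratio estimate from bidirectional samples.

    ``forward`` holds ΔU = U1−U0 sampled in state 0; ``backward`` holds
    ΔU = U0−U1 sampled in state 1. The self-consistent equation

        Σ_i f(M + β(ΔU_f,i − ΔF)) = Σ_j f(−M + β(ΔU_b,j + ΔF))

    with f the logistic function and M = ln(n_f/n_b) is solved by bracketed
    root finding. Returns (ΔF, asymptotic standard error) in kcal/mol.
    """
    wf = np.asarray(forward, dtype=float)
    wb = np.asarray(backward, dtype=float)
    if wf.size < 2 or wb.size < 2:
        raise SpecError("bar requires >= 2 samples in each direction")
    beta = 1.0 / (R_KCAL * temperature)
    m = math.log(wf.size / wb.size)

    def imbalance(df: float) -> float:
        # expit(-x) = 1/(1+e^x): numerically stable logistic sums
        lhs = expit(-(m + beta * (wf - df))).sum()
        rhs = expit(-(-m + beta * (wb + df))).sum()
        return lhs - rhs

    # initial bracket from the two one-sided Zwanzig estimates
    guess_f = zwanzig(wf, temperature)
    guess_b = -zwanzig(wb, temperature)
    lo = min(guess_f, guess_b) - 1.0
    hi = max(guess_f, guess_b) + 1.0
    for _ in range(200):
        if imbalance(lo) * imbalance(hi) <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
    else:
        raise ConvergenceError("bar: no sign change found after bracket expansion")
    df = brentq(imbalance, lo, hi, xtol=tol, rtol=8.9e-16)

    ff = expit(-(m + beta * (wf - df)))
    fb = expit(-(-m + beta * (wb + df)))
    var_beta_df = (
        (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / wf.size
        + (np.mean(fb**2) / np.mean(fb) ** 2 - 1.0) / wb.size
    )
    se = math.sqrt(max(var_beta_df, 0.0)) / beta
    return float(df), float(se)


def mbar(
    u_kn: np.ndarray,
    counts: np.ndarray,
    temperature: float = 300.0,
    tol: float = 1e-10,
    max_iter: int = 200_000,
    damping: float = 1.0,
) -> np.ndarray:
    """Multistate Bennett acceptance ratio free energies.

    Parameters
    ----------
    u_kn
        (K, N) reduced potentials: ``u_kn[k, n]`` is the reduced energy of
        pooled sample n evaluated in state k (dimensionless, i.e. U/kT).
    counts
        length-K sample counts per state; ``sum(counts) == N``.
    temperature
        used only to convert the reduced free energies to kcal/mol.

    Solves the self-consistent MBAR equations

        f_k = −ln Σ_n exp(−u_kn) / Σ_l N_l exp(f_l − u_ln)

    by damped fixed-point iteration until the maximum change in any f_k is
    below ``tol`` (relative to 1 + max|f|). Returns ΔF_k in kcal/mol with
    ΔF_0 ≡ 0.
    """
    u = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(counts, dtype=float)
    if u.ndim != 2:
        raise SpecError("u_kn must be a (K, N) array")
    k_states, n_total = u.shape
    if k_states < 2:
        raise SpecError("mbar requires K >= 2 states")
    if n_k.shape != (k_states,) or n_k.sum() != n_total:
        raise SpecError("counts must be length K and sum to N")
    if not (0 < damping <= 1):
        raise SpecError("damping must lie in (0, 1]")

    log_n = np.log(n_k)
    f = np.zeros(k_states)
    for _ in range(max_iter):
        # log Σ_l N_l exp(f_l − u_ln), per pooled sample n
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = (1.0 - damping) * f + damping * f_new
        if delta < tol * (1.0 + np.max(np.abs(f))):
            return f * R_KCAL * temperature
    raise ConvergenceError(
        f"mbar: not converged after {max_iter} iterations (residual {delta:.3e})"
    )


def stitch_windows(
    window_dfs: np.ndarray, window_vars: np.ndarray | None = None
) -> tuple[float, float]:
    """Total ΔF over a window ladder: sum of per-window estimates.

    Variances add under the independence assumption; returns
    (ΔF_total, SE_total).
    """
    dfs = np.asarray(window_dfs, dtype=float)
    if dfs.size == 0:
        raise SpecError("stitch_windows requires at least one window")
    if window_vars is None:
        var = 0.0
    else:
        var = float(np.sum(np.asarray(window_vars, dtype=float)))
    return float(dfs.sum()), math.sqrt(var)


# ---------------------------------------------------------------------------
# sample containers and plain-text I/O
# ---------------------------------------------------------------------------

@dataclass
class FEPWindow:
    """Bidirectional ΔU samples for one alchemical window (kcal/mol)."""

    forward: np.ndarray
    backward: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if self.forward.size < 2 or self.backward.size < 2:
            raise SpecError("each window direction needs >= 2 samples")


@dataclass
class FEPSamples:
    """Per-window forward/backward ΔU samples for a transformation."""

    windows: list[FEPWindow]
    temperature: float = 300.0

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def _window_mbar_df(window: FEPWindow, temperature: float) -> float:
    """Two-state MBAR ΔF for one window (pooled forward+backward)."""
    beta = 1.0 / (R_KCAL * temperature)
    nf, nb = window.forward.size, window.backward.size
    u = np.zeros((2, nf + nb))
    u[1, :nf] = beta * window.forward   # samples from state 0
    u[0, nf:] = beta * window.backward  # samples from state 1
    f = mbar(u, np.array([nf, nb]), temperature)
    return float(f[1])


def estimate_fep(
    samples: FEPSamples, method: str = "bar"
) -> tuple[float, float, list[float]]:
    """Stitched ΔF over all windows with one estimator.

    method: 'zwanzig' (forward-only exponential averaging), 'bar', or
    'mbar' (two-state MBAR per window, pooling both directions).
    Returns (ΔF_total, SE_total, per-window ΔF list); SE is only available
    for 'bar' (0.0 otherwise).
    """
    dfs: list[float] = []
    variances: list[float] = []
    for w in samples.windows:
        if method == "zwanzig":
            dfs.append(zwanzig(w.forward, samples.temperature))
            variances.append(0.0)
        elif method == "bar":
            df, se = bar(w.forward, w.backward, samples.temperature)
            dfs.append(df)
            variances.append(se**2)
        elif method == "mbar":
            dfs.append(_window_mbar_df(w, samples.temperature))
            variances.append(0.0)
        else:
            raise SpecError(f"unknown estimator {method!r}")
    total, se = stitch_windows(np.array(dfs), np.array(variances))
    return total, se, dfs


def write_fep_table(samples: FEPSamples) -> str:
    """Serialise samples to a TSV with columns window, direction, delta_u."""
    lines = ["window\tdirection\tdelta_u_kcal_mol"]
    for i, w in enumerate(samples.windows):
        lines.extend(f"{i}\tf\t{v:.10g}" for v in w.forward)
        lines.extend(f"{i}\tb\t{v:.10g}" for v in w.backward)
    return "\n".join(lines) + "\n"


def read_fep_table(text: str, temperature: float = 300.0) -> FEPSamples:
    """Parse the TSV produced by :func:`write_fep_table`."""
    fwd: dict[int, list[float]] = {}
    bwd: dict[int, list[float]] = {}
    for lineno, line in enumerate(text.strip().splitlines(), start=1):
        if lineno == 1 and line.lower().startswith("window"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise SpecError(f"fep table line {lineno}: expected 3 columns")
        w, direction, value = int(parts[0]), parts[1], float(parts[2])
        if direction == "f":
            fwd.setdefault(w, []).append(value)
        elif direction == "b":
            bwd.setdefault(w, []).append(value)
        else:
            raise SpecError(f"fep table line {lineno}: direction must be f or b")
    indices = sorted(set(fwd) | set(bwd))
    windows = [
        FEPWindow(np.array(fwd.get(i, [])), np.array(bwd.get(i, [])))
        for i in indices
    ]
    return FEPSamples(windows=windows, temperature=temperature)
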