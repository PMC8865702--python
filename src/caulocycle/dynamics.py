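"""Right-hand side of the cell-cycle ODE system and its building blocks.

The continuous dynamics couple four layers:

* **DNA** — replication initiation progress ``Ini`` (driven by DnaA, opposed by
  CtrA~P, boosted when the origin is fully methylated), fork progress ``Elong``,
  the linear Z-ring clock ``Zring``, and per-locus hemimethylation
  probabilities ``h_*`` that decay as the methyltransferase CcrM accumulates.
* **mRNA** — Hill-regulated transcription of the five master-regulator genes,
  with hemimethylation gating the *ccrM* and *ctrA* (P1) promoters and a
  gene-dosage factor ``(2 - h_Cori)`` on *dnaA*.
* **Proteins** — linear synthesis/degradation for the regulators, plus
  CckA~P-driven phosphorylation of CtrA and Complex3-dependent proteolysis.
* **Protease pathway** — the hierarchical ClpXP adaptor cascade
  (CpdR -> Complex1 -> +RcdA -> Complex2 -> +cdG -> Complex3), the
  PleD/PdeA control of c-di-GMP, and the cdG-inhibited CckA kinase.

PleD phosphorylation is driven by a forcing function fitted to PleC blot time
courses (two equal-frequency sinusoids).  The raw fit is exposed as
:func:`plec_level`; inside the dynamics the forcing is rectified at zero and
its clock restarts at every division event, which is what sustains a stable
limit cycle (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .parameters import PARAM_NAMES, ParameterSet
from .state import STATE_NAMES, CellState

__all__ = ["hill_activation", "hill_inhibition", "plec_level", "derivatives"]

_IP = {name: i for i, name in enumerate(PARAM_NAMES)}

# Parameter-vector indices, resolved once so the compiled kernel can treat them
# as constants.
for _name, _idx in _IP.items():
    globals()["P_" + _name] = _idx

_IS = {name: i for i, name in enumerate(STATE_NAMES)}
for _name, _idx in _IS.items():
    globals()["S_" + _name] = _idx

N_STATES = len(STATE_NAMES)


def hill_activation(x: float, J: float, n: int) -> float:
    """Activatory Hill function x^n / (J^n + x^n).

    Strictly increasing in ``x``, 0 at ``x = 0``, 1/2 at ``x = J`` and -> 1 as
    ``x -> inf``.  ``J`` is the microscopic dissociation constant, ``n`` the
    Hill coefficient.
    """
    if J <= 0:
        raise ValueError(f"dissociation constant must be > 0, got {J}")
    if n < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    out = x**n / (J**n + x**n)
    return float(out) if out.ndim == 0 else out


def hill_inhibition(x: float, J: float, n: int) -> float:
    """Inhibitory Hill function J^n / (J^n + x^n) = 1 - hill_activation."""
    if J <= 0:
        raise ValueError(f"dissociation constant must be > 0, got {J}")
    if n < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    out = J**n / (J**n + x**n)
    return float(out) if out.ndim == 0 else out


def plec_level(t, params: ParameterSet | None = None):
    """PleC phosphatase level at time ``t`` (minutes): the raw fitted function
    A1*sin(omega*t + phi1) + A2*sin(omega*t + phi2)."""
    if params is None:
        from .parameters import default_parameters

        params = default_parameters()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = params.plec_A1 * np.sin(params.plec_omega * t + params.plec_phi1) + \
        params.plec_A2 * np.sin(params.plec_omega * t + params.plec_phi2)
    return float(out) if out.ndim == 0 else out


@njit(cache=False)
def _rhs(t, y, pv, ks_zring, plec_origin, qssa):  # pragma: no cover - compiled
    d = np.zeros(N_STATES)

    Ini = y[S_Ini]; Elong = y[S_Elong]
    hCori = y[S_hCori]; hccrM = y[S_hccrM]; hctrA = y[S_hctrA]
    IccrM = y[S_IccrM]; ccrM = y[S_ccrM]; dnaA = y[S_dnaA]
    gcrA = y[S_gcrA]; sciP = y[S_sciP]; ctrA = y[S_ctrA]
    CcrM = y[S_CcrM]; DnaA = y[S_DnaA]; GcrA = y[S_GcrA]; SciP = y[S_SciP]
    CtrA = y[S_CtrA]; CtrAP = y[S_CtrAP]; CckAP = y[S_CckAP]
    C1 = y[S_Complex1]; CpdR = y[S_CpdR]; CpdRP = y[S_CpdRP]
    C2 = y[S_Complex2]; RcdA = y[S_RcdA]; C3 = y[S_Complex3]
    PleD = y[S_PleD]; PleDP = y[S_PleDP]; PdeA = y[S_PdeA]; cdG = y[S_cdG]

    # --- DNA: initiation, elongation, Z-ring clock, hemimethylation ---
    a4 = (DnaA / pv[P_Theta_DnaA]) ** 4
    b4 = (CtrAP / pv[P_Theta_CtrA]) ** 4
    meth_boost = 1.0 + 1.0 / (pv[P_Ji_Ini] ** 4 + (hCori / pv[P_Theta_Cori]) ** 4)
    d[S_Ini] = pv[P_ks_Ini] * a4 / (pv[P_Ja_Ini] ** 4 + b4 + a4) * meth_boost

    e4 = Elong**4
    d[S_Elong] = pv[P_kelong] * e4 / (e4 + pv[P_Pelong] ** 4)
    d[S_Zring] = ks_zring

    ccrm4 = CcrM**4
    d[S_hCori] = -pv[P_km_Cori] * ccrm4 / (pv[P_Jm_Cori] ** 4 + ccrm4) * hCori
    d[S_hccrM] = -pv[P_km_ccrM] * ccrm4 / (pv[P_Jm_ccrM] ** 4 + ccrm4) * hccrM
    d[S_hctrA] = -pv[P_km_ctrA] * ccrm4 / (pv[P_Jm_ctrA] ** 4 + ccrm4) * hctrA

    # --- mRNA transcription and decay ---
    ctrap2 = CtrAP**2
    d[S_IccrM] = (pv[P_ks_IccrM]
                  * ctrap2 / (pv[P_Ja_ccrM_CtrA] ** 2 + ctrap2)
                  * pv[P_Ji_ccrM_SciP] ** 2 / (pv[P_Ji_ccrM_SciP] ** 2 + SciP**2)
                  * hccrM
                  - pv[P_kd_IccrM] * IccrM)
    d[S_ccrM] = pv[P_ks_ccrM] * IccrM - pv[P_kd_ccrM] * ccrM
    d[S_dnaA] = (pv[P_ks_dnaA]
                 * pv[P_Ji_dnaA_GcrA] ** 2 / (pv[P_Ji_dnaA_GcrA] ** 2 + GcrA**2)
                 * (2.0 - hCori)
                 - pv[P_kd_dnaA] * dnaA)
    d[S_gcrA] = (pv[P_ks_gcrA]
                 * DnaA**2 / (pv[P_Ja_gcrA_DnaA] ** 2 + DnaA**2)
                 * pv[P_Ji_gcrA_CtrA] ** 2 / (pv[P_Ji_gcrA_CtrA] ** 2 + ctrap2)
                 - pv[P_kd_gcrA] * gcrA)
    d[S_sciP] = (pv[P_ks_sciP] * ctrap2 / (pv[P_Ja_sciP_CtrA] ** 2 + ctrap2)
                 - pv[P_kd_sciP] * sciP)
    ctrap4 = ctrap2**2
    d[S_ctrA] = (pv[P_ks1_ctrA]
                 * GcrA**2 / (pv[P_Ja_ctrA_GcrA] ** 2 + GcrA**2)
                 * pv[P_Ji_ctrA_CtrA] ** 4 / (pv[P_Ji_ctrA_CtrA] ** 4 + ctrap4)
                 * pv[P_Ji_ctrA_SciP] ** 4 / (pv[P_Ji_ctrA_SciP] ** 4 + SciP**4)
                 * hctrA
                 + pv[P_ks2_ctrA] * ctrap2 / (pv[P_Ja_ctrA_CtrA] ** 2 + ctrap2)
                 - pv[P_kd_ctrA] * ctrA)

    # --- regulator proteins ---
    d[S_CcrM] = pv[P_ks_CcrM] * ccrM - pv[P_kd_CcrM] * CcrM
    d[S_DnaA] = pv[P_ks_DnaA] * dnaA - pv[P_kd_DnaA] * DnaA
    d[S_GcrA] = pv[P_ks_GcrA] * gcrA - pv[P_kd_GcrA] * GcrA
    d[S_SciP] = pv[P_ks_SciP] * sciP - pv[P_kd_SciP] * SciP

    if qssa:
        C3 = pv[P_k3_plus] * cdG**2 * C2 / pv[P_k3_minus]

    deg_ctra = pv[P_kd_CtrA] + pv[P_kd_CtrA_ClpXP] * C3**2 / (pv[P_Jd_CtrA_ClpXP] ** 2 + C3**2)
    pho = pv[P_kphos_CtrA] * CckAP * CtrA
    depho = pv[P_kdephos_CtrA] * CtrAP
    d[S_CtrA] = pv[P_ks_CtrA] * ctrA - deg_ctra * CtrA - pho + depho
    d[S_CtrAP] = -deg_ctra * CtrAP + pho - depho

    # --- protease pathway ---
    d[S_CckAP] = (pv[P_kphos_CckA] * (pv[P_CckA_T] - CckAP)
                  - pv[P_kdephos_CckA] * (1.0 + pv[P_alpha_cdG] * cdG) * CckAP)

    bind1 = pv[P_k1_plus] * pv[P_ClpXP] * CpdR
    d[S_Complex1] = (bind1 - pv[P_k1_minus] * C1
                     - pv[P_k2_plus] * C1 * RcdA + pv[P_k2_minus] * C2)

    mm1 = C1 / (pv[P_Jd_CpdR] + C1)
    pho_cpdr = pv[P_kphos_CpdR] * CckAP * CpdR
    d[S_CpdR] = (pv[P_ks_CpdR] * ctrap2 / (pv[P_Ja_CpdR_CtrA] ** 2 + ctrap2)
                 - pv[P_kd_CpdR] * CpdR * mm1
                 + pv[P_k1_minus] * C1 - bind1
                 + pv[P_kdephos_CpdR] * CpdRP - pho_cpdr)
    d[S_CpdRP] = (-pv[P_kd_CpdR] * CpdRP * mm1
                  + pho_cpdr - pv[P_kdephos_CpdR] * CpdRP)

    bind3 = pv[P_k3_plus] * cdG**2 * C2
    unbind3 = pv[P_k3_minus] * C3
    d[S_Complex2] = (pv[P_k2_plus] * C1 * RcdA - pv[P_k2_minus] * C2
                     + unbind3 - bind3)
    d[S_RcdA] = (pv[P_ks_RcdA] * ctrap2 / (pv[P_Ja_RcdA_CtrA] ** 2 + ctrap2)
                 - pv[P_kd_RcdA] * RcdA * C1 / (pv[P_Jd_RcdA] + C1))
    d[S_Complex3] = 0.0 if qssa else bind3 - unbind3

    # PleC forcing: raw fit, rectified at 0, clock anchored at the last division
    tl = t - plec_origin
    plec = (pv[P_plec_A1] * np.sin(pv[P_plec_omega] * tl + pv[P_plec_phi1])
            + pv[P_plec_A2] * np.sin(pv[P_plec_omega] * tl + pv[P_plec_phi2]))
    if plec < 0.0:
        plec = 0.0
    transfer = pv[P_kphos_PleD] * PleD - pv[P_kdephos_PleD] * plec * PleDP
    d[S_PleD] = (pv[P_ks_PleD] * ctrap2 / (pv[P_Ja_PleD_CtrA] ** 2 + ctrap2)
                 - pv[P_kd_PleD] * PleD - transfer)
    d[S_PleDP] = transfer

    d[S_PdeA] = (pv[P_ks_PdeA] * ctrap2 / (pv[P_Ja_PdeA_CtrA] ** 2 + ctrap2)
                 - pv[P_kd_PdeA] * PdeA * C1 / (pv[P_Jd_PdeA] + C1))

    d[S_cdG] = (pv[P_ks_cdG] * (1.0 + pv[P_alpha_PleD] * PleD)
                * pv[P_Ji_cdG_cdG] ** 2 / (pv[P_Ji_cdG_cdG] ** 2 + cdG**2)
                - pv[P_kd_cdG] * (1.0 + pv[P_alpha_PdeA] * PdeA) * cdG
                + unbind3 - bind3)
    return d


def derivatives(t: float, state: CellState, params: ParameterSet, *,
                qssa: bool = False, plec_origin: float = 0.0) -> np.ndarray:
    """Instantaneous rate of change of every continuous state variable.

    Parameters
    ----------
    t : float
        Absolute time in minutes.
    state : CellState
        Current state; must be non-negative and finite (domain error otherwise).
    params : ParameterSet
        Kinetic constants.
    qssa : bool
        If True, Complex3 is taken at its quasi-steady state
        ``k3+ cdG^2 Complex2 / k3-`` and its own derivative is zero.
    plec_origin : float
        Absolute time of the last division event; the PleC forcing clock is
        anchored there.

    Returns
    -------
    numpy.ndarray
        Rates in ``STATE_NAMES`` order, a.u. per minute.
    """
    state.validate()
    if t < plec_origin:
        raise ValueError("t must not precede the PleC clock origin")
    return _rhs(float(t), state.y, params.to_vector(), state.ks_zring,
                float(plec_origin), bool(qssa))
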