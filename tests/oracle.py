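"""Independent, term-by-term transcription of the model equations.

Plain-Python reference used only as a cross-check oracle for the package's
compiled right-hand side; deliberately written equation by equation, not
shared with the implementation.
"""

import numpy as np

STATE_ORDER = (
    "Ini", "Elong", "Zring", "hCori", "hccrM", "hctrA",
    "IccrM", "ccrM", "dnaA", "gcrA", "sciP", "ctrA",
    "CcrM", "DnaA", "GcrA", "SciP", "CtrA", "CtrAP",
    "CckAP", "Complex1", "CpdR", "CpdRP", "Complex2", "RcdA", "Complex3",
    "PleD", "PleDP", "PdeA", "cdG",
)


def reference_rhs(t, state, p, ks_zring=0.0, plec_origin=0.0):
    """state and p are plain name->value dicts; returns a name->rate dict."""
    s = state
    d = {}

    # replication initiation: DnaA-activated, CtrA~P-inhibited, boosted on a
    # fully methylated origin
    num = (s["DnaA"] / p["Theta_DnaA"]) ** 4
    den = p["Ja_Ini"] ** 4 + (s["CtrAP"] / p["Theta_CtrA"]) ** 4 + num
    boost = 1 + 1 / (p["Ji_Ini"] ** 4 + (s["hCori"] / p["Theta_Cori"]) ** 4)
    d["Ini"] = p["ks_Ini"] * (num / den) * boost

    d["Elong"] = p["kelong"] * s["Elong"] ** 4 / (s["Elong"] ** 4 + p["Pelong"] ** 4)
    d["Zring"] = ks_zring

    def remeth(km, Jm):
        return km * s["CcrM"] ** 4 / (Jm**4 + s["CcrM"] ** 4)

    d["hCori"] = -remeth(p["km_Cori"], p["Jm_Cori"]) * s["hCori"]
    d["hccrM"] = -remeth(p["km_ccrM"], p["Jm_ccrM"]) * s["hccrM"]
    d["hctrA"] = -remeth(p["km_ctrA"], p["Jm_ctrA"]) * s["hctrA"]

    def act(x, J, n=2):
        return x**n / (J**n + x**n)

    def inh(x, J, n=2):
        return J**n / (J**n + x**n)

    d["IccrM"] = (p["ks_IccrM"] * act(s["CtrAP"], p["Ja_ccrM_CtrA"])
                  * inh(s["SciP"], p["Ji_ccrM_SciP"]) * s["hccrM"]
                  - p["kd_IccrM"] * s["IccrM"])
    d["ccrM"] = p["ks_ccrM"] * s["IccrM"] - p["kd_ccrM"] * s["ccrM"]
    d["dnaA"] = (p["ks_dnaA"] * inh(s["GcrA"], p["Ji_dnaA_GcrA"]) * (2 - s["hCori"])
                 - p["kd_dnaA"] * s["dnaA"])
    d["gcrA"] = (p["ks_gcrA"] * act(s["DnaA"], p["Ja_gcrA_DnaA"])
                 * inh(s["CtrAP"], p["Ji_gcrA_CtrA"]) - p["kd_gcrA"] * s["gcrA"])
    d["sciP"] = p["ks_sciP"] * act(s["CtrAP"], p["Ja_sciP_CtrA"]) - p["kd_sciP"] * s["sciP"]
    d["ctrA"] = (p["ks1_ctrA"] * act(s["GcrA"], p["Ja_ctrA_GcrA"])
                 * inh(s["CtrAP"], p["Ji_ctrA_CtrA"], 4)
                 * inh(s["SciP"], p["Ji_ctrA_SciP"], 4) * s["hctrA"]
                 + p["ks2_ctrA"] * act(s["CtrAP"], p["Ja_ctrA_CtrA"])
                 - p["kd_ctrA"] * s["ctrA"])

    d["CcrM"] = p["ks_CcrM"] * s["ccrM"] - p["kd_CcrM"] * s["CcrM"]
    d["DnaA"] = p["ks_DnaA"] * s["dnaA"] - p["kd_DnaA"] * s["DnaA"]
    d["GcrA"] = p["ks_GcrA"] * s["gcrA"] - p["kd_GcrA"] * s["GcrA"]
    d["SciP"] = p["ks_SciP"] * s["sciP"] - p["kd_SciP"] * s["SciP"]

    deg = p["kd_CtrA"] + p["kd_CtrA_ClpXP"] * act(s["Complex3"], p["Jd_CtrA_ClpXP"])
    d["CtrA"] = (p["ks_CtrA"] * s["ctrA"] - deg * s["CtrA"]
                 - p["kphos_CtrA"] * s["CckAP"] * s["CtrA"]
                 + p["kdephos_CtrA"] * s["CtrAP"])
    d["CtrAP"] = (-deg * s["CtrAP"] + p["kphos_CtrA"] * s["CckAP"] * s["CtrA"]
                  - p["kdephos_CtrA"] * s["CtrAP"])

    d["CckAP"] = (p["kphos_CckA"] * (p["CckA_T"] - s["CckAP"])
                  - p["kdephos_CckA"] * (1 + p["alpha_cdG"] * s["cdG"]) * s["CckAP"])

    d["Complex1"] = (p["k1_plus"] * p["ClpXP"] * s["CpdR"]
                     - p["k1_minus"] * s["Complex1"]
                     - p["k2_plus"] * s["Complex1"] * s["RcdA"]
                     + p["k2_minus"] * s["Complex2"])

    sat1 = s["Complex1"] / (p["Jd_CpdR"] + s["Complex1"])
    d["CpdR"] = (p["ks_CpdR"] * act(s["CtrAP"], p["Ja_CpdR_CtrA"])
                 - p["kd_CpdR"] * s["CpdR"] * sat1
                 + p["k1_minus"] * s["Complex1"]
                 - p["k1_plus"] * p["ClpXP"] * s["CpdR"]
                 + p["kdephos_CpdR"] * s["CpdRP"]
                 - p["kphos_CpdR"] * s["CckAP"] * s["CpdR"])
    d["CpdRP"] = (-p["kd_CpdR"] * s["CpdRP"] * sat1
                  + p["kphos_CpdR"] * s["CckAP"] * s["CpdR"]
                  - p["kdephos_CpdR"] * s["CpdRP"])

    d["Complex2"] = (p["k2_plus"] * s["Complex1"] * s["RcdA"]
                     - p["k2_minus"] * s["Complex2"]
                     + p["k3_minus"] * s["Complex3"]
                     - p["k3_plus"] * s["cdG"] ** 2 * s["Complex2"])
    d["RcdA"] = (p["ks_RcdA"] * act(s["CtrAP"], p["Ja_RcdA_CtrA"])
                 - p["kd_RcdA"] * s["RcdA"] * s["Complex1"] / (p["Jd_RcdA"] + s["Complex1"]))
    d["Complex3"] = (p["k3_plus"] * s["cdG"] ** 2 * s["Complex2"]
                     - p["k3_minus"] * s["Complex3"])

    tl = t - plec_origin
    plec = (p["plec_A1"] * np.sin(p["plec_omega"] * tl + p["plec_phi1"])
            + p["plec_A2"] * np.sin(p["plec_omega"] * tl + p["plec_phi2"]))
    plec = max(plec, 0.0)
    d["PleD"] = (p["ks_PleD"] * act(s["CtrAP"], p["Ja_PleD_CtrA"])
                 - p["kd_PleD"] * s["PleD"] - p["kphos_PleD"] * s["PleD"]
                 + p["kdephos_PleD"] * plec * s["PleDP"])
    d["PleDP"] = p["kphos_PleD"] * s["PleD"] - p["kdephos_PleD"] * plec * s["PleDP"]

    d["PdeA"] = (p["ks_PdeA"] * act(s["CtrAP"], p["Ja_PdeA_CtrA"])
                 - p["kd_PdeA"] * s["PdeA"] * s["Complex1"] / (p["Jd_PdeA"] + s["Complex1"]))

    d["cdG"] = (p["ks_cdG"] * (1 + p["alpha_PleD"] * s["PleD"])
                * inh(s["cdG"], p["Ji_cdG_cdG"])
                - p["kd_cdG"] * (1 + p["alpha_PdeA"] * s["PdeA"]) * s["cdG"]
                + p["k3_minus"] * s["Complex3"]
                - p["k3_plus"] * s["cdG"] ** 2 * s["Complex2"])

    return np.array([d[name] for name in STATE_ORDER])
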