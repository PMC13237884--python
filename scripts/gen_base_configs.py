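"""Emit the packaged base-case YAML configs (overall / dmmr / pmmr).

Run from repo root:  python scripts/gen_base_configs.py
"""

import copy
from pathlib import Path

import yaml

OUT = Path(__file__).resolve().parents[1] / "src" / "psmkit" / "configs"

SFDA = "SFDA drug tariff, per 21-day cycle, 2025 USD"
SEE = "structured expert elicitation (pooled beta-PERT; range = across-expert IQR)"
TRIAL_INC = "index-trial grade>=3 AE incidence (range +/-20%)"
LIT_UTIL = "published EQ-5D utility set (range +/-20%)"
LIT_DIS = "published one-off AE disutility (range +/-20%)"
ASSUMED = "assumption: trial utilization rates unpublished; documented default"

AE_NAMES = [
    "anemia",
    "neutropenia",
    "neutrophil_count_decreased",
    "lymphocyte_count_decreased",
    "white_cell_count_decreased",
    "hypertension",
    "pulmonary_embolism",
    "hypokalemia",
]

AE_COSTS = {  # (base, Q1, Q3)
    "anemia": (1371.15, 708.15, 2034.15),
    "neutropenia": (2076.54, 1569.54, 2583.54),
    "neutrophil_count_decreased": (2176.54, 1735.54, 2617.54),
    "lymphocyte_count_decreased": (1275.43, 900.43, 1650.43),
    "white_cell_count_decreased": (1108.02, 766.02, 1450.02),
    "hypertension": (688.39, 226.39, 1150.39),
    "pulmonary_embolism": (897.57, 762.57, 1032.57),
    "hypokalemia": (311.09, 260.09, 362.09),
}

AE_DISUTIL = {  # (base, lo, hi) stored as negatives; lo = smaller magnitude
    "anemia": (-0.073, -0.0584, -0.0876),
    "neutropenia": (-0.09, -0.072, -0.108),
    "neutrophil_count_decreased": (-0.09, -0.072, -0.108),
    "lymphocyte_count_decreased": (-0.09, -0.072, -0.108),
    "white_cell_count_decreased": (-0.09, -0.072, -0.108),
    "hypertension": (-0.05, -0.04, -0.06),
    "pulmonary_embolism": (-0.1, -0.08, -0.12),
    "hypokalemia": (-0.05, -0.04, -0.06),
}

AE_INC = {
    "dsr_cp": {
        "anemia": (0.149, 0.1192, 0.1788),
        "neutropenia": (0.095, 0.076, 0.114),
        "neutrophil_count_decreased": (0.083, 0.0664, 0.0996),
        "lymphocyte_count_decreased": (0.054, 0.0432, 0.0648),
        "white_cell_count_decreased": (0.066, 0.0528, 0.0792),
        "hypertension": (0.071, 0.0568, 0.0852),
        "pulmonary_embolism": (0.05, 0.04, 0.06),
        "hypokalemia": (0.05, 0.04, 0.06),
    },
    "pbo_cp": {
        "anemia": (0.163, 0.1304, 0.1956),
        "neutropenia": (0.093, 0.0744, 0.1116),
        "neutrophil_count_decreased": (0.138, 0.1104, 0.1656),
        "lymphocyte_count_decreased": (0.073, 0.0584, 0.0876),
        "white_cell_count_decreased": (0.053, 0.0424, 0.0636),
        "hypertension": (0.033, 0.0264, 0.0396),
        "pulmonary_embolism": (0.049, 0.0392, 0.0588),
        "hypokalemia": (0.037, 0.0296, 0.0444),
    },
}

SURVIVAL = {
    "overall": {
        "dsr_cp": {
            "pfs": ("weibull", {"scale": 21.4562, "shape": 1.0189}),
            "os": ("gompertz", {"shape": 0.0008, "rate": 0.0153}),
        },
        "pbo_cp": {
            "pfs": ("lognormal", {"mu": 2.2501, "sigma": 0.9401}),
            "os": ("weibull", {"scale": 38.3971, "shape": 1.3501}),
        },
    },
    "dmmr": {
        "dsr_cp": {
            "pfs": ("gengamma", {"mu": 3.8011, "sigma": 1.4753, "Q": 0.6576}),
            "os": ("gompertz", {"shape": 0.0001, "rate": 0.0083}),
        },
        "pbo_cp": {
            "pfs": ("loglogistic", {"scale": 8.0441, "shape": 1.9689}),
            "os": ("weibull", {"scale": 40.0051, "shape": 1.1549}),
        },
    },
    "pmmr": {
        "dsr_cp": {
            "pfs": ("gengamma", {"mu": 2.8385, "sigma": 0.8319, "Q": 0.8787}),
            "os": ("gompertz", {"shape": 0.0206, "rate": 0.0131}),
        },
        "pbo_cp": {
            "pfs": ("weibull", {"scale": 14.2913, "shape": 1.1681}),
            "os": ("weibull", {"scale": 35.9261, "shape": 1.3603}),
        },
    },
}

# subsequent-therapy mixes per population (PBO arm gets active subsequent
# therapy incl. immunotherapy; DSR arm is assumed to get chemo only).
# Durations = published median PFS of the referenced subsequent-line trials.
PEMBRO_DUR = 13.1  # pembrolizumab monotherapy, dMMR/MSI-H EC
LENPEM_DUR = 7.2  # lenvatinib + pembrolizumab
DOX_DUR = 3.8  # single-agent chemotherapy (doxorubicin)
DMMR_SHARE = 0.24  # dMMR prevalence in the index trial population

SUBSEQUENT = {
    "overall": {
        "pbo_cp": [
            {"share": DMMR_SHARE, "cost_keys": ["cost_pembrolizumab"], "duration_months": PEMBRO_DUR},
            {"share": round((1 - DMMR_SHARE) / 2, 2), "cost_keys": ["cost_pembrolizumab", "cost_lenvatinib"], "duration_months": LENPEM_DUR},
            {"share": round((1 - DMMR_SHARE) / 2, 2), "cost_keys": ["cost_doxorubicin"], "duration_months": DOX_DUR},
        ],
        "dsr_cp": [
            {"share": 1.0, "cost_keys": ["cost_doxorubicin"], "duration_months": DOX_DUR}
        ],
    },
    "dmmr": {
        "pbo_cp": [
            {"share": 1.0, "cost_keys": ["cost_pembrolizumab"], "duration_months": PEMBRO_DUR}
        ],
        "dsr_cp": [
            {"share": 1.0, "cost_keys": ["cost_doxorubicin"], "duration_months": DOX_DUR}
        ],
    },
    "pmmr": {
        "pbo_cp": [
            {"share": 0.5, "cost_keys": ["cost_pembrolizumab", "cost_lenvatinib"], "duration_months": LENPEM_DUR},
            {"share": 0.5, "cost_keys": ["cost_doxorubicin"], "duration_months": DOX_DUR},
        ],
        "dsr_cp": [
            {"share": 1.0, "cost_keys": ["cost_doxorubicin"], "duration_months": DOX_DUR}
        ],
    },
}


def build_values():
    v = {}
    for key, base in [
        ("cost_dostarlimab", 7460.19),
        ("cost_pembrolizumab", 3130.26),
        ("cost_paclitaxel", 5267.60),
        ("cost_carboplatin", 375.08),
        ("cost_lenvatinib", 6879.19),
        ("cost_doxorubicin", 2197.54),
    ]:
        v[key] = {"base": base, "family": "gamma", "rel_range": 0.30, "role": "cost", "source": SFDA}
    v["cost_bsc"] = {"base": 2200.0, "lo": 1030.0, "hi": 3370.0, "family": "beta_pert", "role": "cost", "source": SEE}
    v["cost_followup"] = {"base": 3843.45, "lo": 2976.45, "hi": 4710.45, "family": "beta_pert", "role": "cost", "source": SEE}
    for name in AE_NAMES:
        base, q1, q3 = AE_COSTS[name]
        v[f"cost_ae_{name}"] = {"base": base, "lo": q1, "hi": q3, "family": "beta_pert", "role": "cost", "source": SEE}
        d, dlo, dhi = AE_DISUTIL[name]
        v[f"dis_{name}"] = {"base": d, "lo": dlo, "hi": dhi, "family": "beta", "role": "disutility", "source": LIT_DIS}
        for arm, tag in (("dsr_cp", "dsr"), ("pbo_cp", "pbo")):
            base_i, lo_i, hi_i = AE_INC[arm][name]
            v[f"inc_{tag}_{name}"] = {"base": base_i, "lo": lo_i, "hi": hi_i, "family": "beta", "role": "probability", "source": TRIAL_INC}
    v["u_pfs"] = {"base": 0.817, "lo": 0.6536, "hi": 0.9804, "family": "beta", "role": "utility", "source": LIT_UTIL}
    v["u_pd"] = {"base": 0.779, "lo": 0.6232, "hi": 0.9348, "family": "beta", "role": "utility", "source": LIT_UTIL}
    v["uptake_dsr"] = {"base": 0.40, "family": "beta", "rel_range": 0.20, "role": "probability", "source": ASSUMED}
    v["uptake_pbo"] = {"base": 0.60, "family": "beta", "rel_range": 0.20, "role": "probability", "source": ASSUMED}
    return v


def arm_structure(pop, arm, tag):
    induction = ["cost_paclitaxel", "cost_carboplatin"]
    maintenance = []
    if arm == "dsr_cp":
        induction = ["cost_dostarlimab"] + induction
        maintenance = ["cost_dostarlimab"]
    return {
        "induction_drug_keys": induction,
        "n_induction_cycles": 6,
        "maintenance_drug_keys": maintenance,
        "maintenance_cap_years": 3.0,
        "followup_key": "cost_followup",
        "bsc_key": "cost_bsc",
        "uptake_key": f"uptake_{tag}",
        "subsequent": SUBSEQUENT[pop][arm],
        "ae": [
            {
                "name": name,
                "incidence_key": f"inc_{tag}_{name}",
                "cost_key": f"cost_ae_{name}",
                "disutility_key": f"dis_{name}",
            }
            for name in AE_NAMES
        ],
    }


def build(pop):
    surv = {}
    for arm, eps in SURVIVAL[pop].items():
        surv[arm] = {}
        for ep, (family, params) in eps.items():
            surv[arm][ep] = {
                "family": family,
                "params": params,
                "time_unit": "months",
                "source": f"fitted {ep.upper()} extrapolation, {pop} population, {arm}",
            }
    return {
        "name": pop,
        "intervention": "dsr_cp",
        "comparator": "pbo_cp",
        "settings": {
            "cycle_days": 21.0,
            "horizon_years": 16.0,
            "discount_annual": 0.03,
            "wtp": 90000.0,
            "start_age": 64.0,
            "evaluation": "midpoint",
        },
        "survival": surv,
        "values": build_values(),
        "arms": {
            "dsr_cp": arm_structure(pop, "dsr_cp", "dsr"),
            "pbo_cp": arm_structure(pop, "pbo_cp", "pbo"),
        },
        "utilities": {"pfs_key": "u_pfs", "pd_key": "u_pd"},
    }


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    for pop in ("overall", "dmmr", "pmmr"):
        doc = build(pop)
        with open(OUT / f"{pop}.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, width=100)
        print("wrote", OUT / f"{pop}.yaml")
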