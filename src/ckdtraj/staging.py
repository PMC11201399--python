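"""eGFR estimation (CKD-EPI 2009 creatinine equation) and KDIGO staging.

The glomerular filtration rate is estimated from serum creatinine, age
and sex with the 2009 CKD-EPI creatinine equation.  The race coefficient
of the original equation is omitted entirely (it is not configurable):
the package targets registry data where ethnicity is not recorded.

KDIGO G stages partition the eGFR axis into six categories G1..G5 with
G3 split into G3A/G3B.  Band edges are half-open intervals
``[lower, upper)`` so every non-negative eGFR value maps to exactly one
stage; the top band G1 is ``[90, inf)``.  A coarser three-state space
(G1/2, G3, G4/5) is used by the simplified process maps and by the
multistate model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STAGES",
    "MERGED_STAGES",
    "STAGE_EDGES",
    "MERGE_MAP",
    "SCR_UMOL_PER_MGDL",
    "umol_to_mgdl",
    "compute_egfr",
    "scr_for_egfr",
    "assign_stage",
    "merge_stage",
]

#: KDIGO G-stage labels ordered from best to worst kidney function.
STAGES = ("G1", "G2", "G3A", "G3B", "G4", "G5")

#: Coarsened stage labels used by the simplified process maps and the
#: multistate model, ordered from best to worst.
MERGED_STAGES = ("G1/2", "G3", "G4/5")

#: Interior band edges on the eGFR axis (mL/min/1.73 m²); stages are the
#: half-open intervals between consecutive edges, G5 = [0, 15) .. G1 = [90, inf).
STAGE_EDGES = (15.0, 30.0, 45.0, 60.0, 90.0)

MERGE_MAP = {
    "G1": "G1/2",
    "G2": "G1/2",
    "G3A": "G3",
    "G3B": "G3",
    "G4": "G4/5",
    "G5": "G4/5",
}

#: Conversion factor between µmol/L (Swedish laboratory reporting) and
#: mg/dL (the unit the CKD-EPI constants are calibrated for).
SCR_UMOL_PER_MGDL = 88.4

# labels indexed by np.searchsorted(STAGE_EDGES, egfr, side="right")
_LABELS_BY_BAND = np.array(["G5", "G4", "G3B", "G3A", "G2", "G1"])

# CKD-EPI 2009 sex-specific constants (creatinine in mg/dL)
_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.329, "male": -0.411}
_SEX_FACTOR = {"female": 1.018, "male": 1.0}


def umol_to_mgdl(scr_umol):
    """Convert serum creatinine from µmol/L to mg/dL (divide by 88.4)."""
    return np.asarray(scr_umol, dtype=float) / SCR_UMOL_PER_MGDL


def _normalise_sex(sex) -> np.ndarray:
    raw = np.asarray(sex)
    flat = np.char.lower(raw.astype(str))
    out = np.where(np.char.startswith(flat, "f"), "female",
                   np.where(np.char.startswith(flat, "m"), "male", ""))
    if np.any(out == ""):
        bad = sorted(set(raw[out == ""].tolist()))
        raise ValueError(f"unrecognised sex value(s): {bad!r}")
    return out


def compute_egfr(scr_mgdl, age, sex):
    """Estimated GFR (mL/min/1.73 m²) from the CKD-EPI 2009 equation.

    ``141 * min(scr/k, 1)^a * max(scr/k, 1)^-1.209 * 0.993^age * 1.018[female]``
    with ``k = 0.7 (female) / 0.9 (male)`` and ``a = -0.329 / -0.411``.
    No race coefficient.

    Parameters
    ----------
    scr_mgdl : float or array-like
        Serum creatinine in mg/dL, strictly positive.
    age : float or array-like
        Age in years; the equation applies to adults (>= 18).
    sex : str or array-like
        ``"female"``/``"male"`` (initial letter suffices, case-insensitive).

    Returns
    -------
    float or ndarray
        eGFR in mL/min/1.73 m²; strictly decreasing in creatinine and in age.
    """
    scr = np.asarray(scr_mgdl, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(scr)) or np.any(scr <= 0):
        raise ValueError("serum creatinine must be finite and strictly positive")
    if np.any(~np.isfinite(age_a)) or np.any(age_a < 18):
        raise ValueError("age must be finite and >= 18 (adult equation)")
    sex_n = _normalise_sex(sex)

    kappa = np.where(sex_n == "female", _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(sex_n == "female", _ALPHA["female"], _ALPHA["male"])
    sexf = np.where(sex_n == "female", _SEX_FACTOR["female"], _SEX_FACTOR["male"])

    ratio = scr / kappa
    egfr = (141.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** age_a
            * sexf)
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def scr_for_egfr(egfr, age, sex):
    """Serum creatinine (mg/dL) that yields a given eGFR — the inverse of
    :func:`compute_egfr` for fixed age and sex.

    The equation is strictly decreasing in creatinine, so the inverse is
    unique: for eGFR below the value at ``scr = kappa`` the steep branch
    (exponent −1.209) applies, above it the shallow sex-specific branch.
    Used by the simulator to emit creatinine that stages back to a chosen
    eGFR band.
    """
    egfr_a = np.asarray(egfr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(egfr_a <= 0):
        raise ValueError("egfr must be strictly positive to invert")
    sex_n = _normalise_sex(sex)
    kappa = np.where(sex_n == "female", _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(sex_n == "female", _ALPHA["female"], _ALPHA["male"])
    sexf = np.where(sex_n == "female", _SEX_FACTOR["female"], _SEX_FACTOR["male"])
    base = 141.0 * 0.993 ** age_a * sexf  # eGFR at scr == kappa
    ratio = egfr_a / base
    scr = np.where(ratio <= 1.0,
                   kappa * ratio ** (-1.0 / 1.209),
                   kappa * ratio ** (1.0 / alpha))
    if scr.ndim == 0:
        return float(scr)
    return scr


def assign_stage(egfr):
    """Map eGFR value(s) to the KDIGO stage label.

    Bands are half-open: G5 [0,15), G4 [15,30), G3B [30,45), G3A [45,60),
    G2 [60,90), G1 [90, inf).  Negative values are rejected.
    """
    egfr_a = np.asarray(egfr, dtype=float)
    if np.any(~np.isfinite(egfr_a)) or np.any(egfr_a < 0):
        raise ValueError("egfr must be finite and non-negative")
    idx = np.searchsorted(np.asarray(STAGE_EDGES), egfr_a, side="right")
    labels = _LABELS_BY_BAND[idx]
    if labels.ndim == 0:
        return str(labels)
    return labels


def merge_stage(stage):
    """Coarsen full KDIGO stage label(s) to {G1/2, G3, G4/5}."""
    stage_a = np.asarray(stage)
    if stage_a.ndim == 0:
        try:
            return MERGE_MAP[str(stage_a)]
        except KeyError:
            raise ValueError(f"unknown stage label {stage!r}") from None
    flat = stage_a.astype(str)
    unknown = set(flat.ravel().tolist()) - set(MERGE_MAP)
    if unknown:
        raise ValueError(f"unknown stage label(s): {sorted(unknown)!r}")
    merged = np.array([MERGE_MAP[s] for s in flat.ravel()], dtype="U4")
    return merged.reshape(flat.shape)
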