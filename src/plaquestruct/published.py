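"""Published three-patient reference summary used as comparison inputs.

Per-patient summary measurements reported for three carotid-endarterectomy
patients with similar (81-83%) ICA stenosis, from the clinical
multi-contrast-MRI + fluid-structure-interaction study this pipeline
emulates: plaque-component volumes and thinnest fibrous cap from
segmentation, TAWSS statistics over an apex-anchored 17 mm ICA region of
interest, and maximum-principal-stress statistics over a 13 mm window
centered on the peak-stress plane. These printed values are inputs to the
cross-patient comparison arithmetic (`wallstress.compare_patients`); the
derived comparison figures quoted alongside allow the arithmetic to be
checked against the originally printed ratios.
"""
from __future__ import annotations

PATIENT_SUMMARIES: list[dict] = [
    {
        "case_id": "patient1",
        "stenosis_percent": 81.0,
        "calcification_volume_mm3": 3.44,
        "lipid_volume_mm3": 42.79,
        "thinnest_cap_mm": 0.729,
        "tawss_roi_mean_pa": 5.45,
        "tawss_roi_sd_pa": 6.44,
        "stress_p1_max_kpa": 133.1,
        "stress_roi_mean_kpa": 22.221,
        "stress_roi_sd_kpa": 16.579,
    },
    {
        "case_id": "patient2",
        "stenosis_percent": 83.0,
        "calcification_volume_mm3": 77.38,
        "lipid_volume_mm3": 48.59,
        "thinnest_cap_mm": 1.186,
        "tawss_roi_mean_pa": 14.62,
        "tawss_roi_sd_pa": 13.72,
        "stress_p1_max_kpa": 116.9,
        "stress_roi_mean_kpa": 13.098,
        "stress_roi_sd_kpa": 20.378,
    },
    {
        "case_id": "patient3",
        "stenosis_percent": 82.0,
        "calcification_volume_mm3": 10.43,
        "lipid_volume_mm3": 236.79,
        "thinnest_cap_mm": 0.676,
        "tawss_roi_mean_pa": 6.99,
        "tawss_roi_sd_pa": 6.34,
        "stress_p1_max_kpa": 127.4,
        "stress_roi_mean_kpa": 21.075,
        "stress_roi_sd_kpa": 17.391,
    },
]

#: Comparison figures as printed in the original report, keyed by
#: (metric, larger case, smaller case). Volume folds and stress percent
#: differences were printed truncated; TAWSS folds rounded.
PUBLISHED_COMPARISONS: dict[tuple[str, str, str], float] = {
    ("calcification_volume_mm3", "patient2", "patient1"): 22.4,
    ("calcification_volume_mm3", "patient2", "patient3"): 7.4,
    ("lipid_volume_mm3", "patient3", "patient1"): 5.5,
    ("lipid_volume_mm3", "patient3", "patient2"): 4.87,
    ("tawss_roi_mean_pa", "patient2", "patient1"): 2.7,
    ("tawss_roi_mean_pa", "patient2", "patient3"): 2.1,
    ("stress_p1_max_kpa", "patient1", "patient2"): 13.8,
    ("stress_p1_max_kpa", "patient3", "patient2"): 8.9,
}

#: ROI conventions of the source study (mm).
TAWSS_ROI_LENGTH_MM = 17.0
STRESS_ROI_LENGTH_MM = 13.0
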