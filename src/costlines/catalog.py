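"""ACRG3 morbidity catalogue and the published population mix.

The ACRG3 level of the Clinical Risk Groups system crosses a health status
(1 Healthy ... 9 Catastrophic) with a severity level (0-6).  Individuals
arrive pre-classified; this module only carries the catalogue of populated
cells and the cross-sectional population percentages used as the default
category mix of the synthetic cohort generator.
"""

from __future__ import annotations

HEALTH_STATUS_NAMES = {
    1: "Healthy",
    2: "History of significant acute disease",
    3: "Single minor chronic disease",
    4: "Minor chronic disease in multiple organ systems",
    5: "Single dominant or moderate chronic disease",
    6: "Significant chronic disease in multiple organ systems",
    7: "Dominant chronic disease in three or more organ systems",
    8: "Dominant, metastatic, and complicated malignancies",
    9: "Catastrophic conditions",
}

# Population percent per populated (status, severity) cell of the published
# cross-sectional mix (N = 92,498; severity 0 exists only for statuses 1-2).
TABLE1_PERCENT: dict[str, float] = {
    "1-0": 32.65, "1-1": 16.95, "1-2": 0.26, "1-4": 0.31, "1-5": 1.50,
    "2-0": 4.65, "2-2": 0.54, "2-4": 0.16, "2-5": 1.31,
    "3-1": 6.67, "3-2": 2.10,
    "4-1": 1.07, "4-2": 0.17, "4-3": 1.01, "4-4": 0.48,
    "5-1": 9.16, "5-2": 2.79, "5-3": 0.75, "5-4": 0.05, "5-5": 0.09,
    "5-6": 0.01,
    "6-1": 6.75, "6-2": 3.12, "6-3": 2.52, "6-4": 1.73, "6-5": 0.64,
    "6-6": 0.09,
    "7-1": 0.29, "7-2": 0.26, "7-3": 0.60, "7-4": 0.16, "7-5": 0.12,
    "7-6": 0.03,
    "8-1": 0.06, "8-2": 0.19, "8-3": 0.23, "8-4": 0.15, "8-5": 0.03,
    "9-1": 0.02, "9-2": 0.10, "9-3": 0.06, "9-4": 0.06, "9-5": 0.03,
    "9-6": 0.05,
}

#: Catalogue of valid ACRG3 labels (the populated cells above).
ACRG3_CATALOG: tuple[str, ...] = tuple(TABLE1_PERCENT)

#: Baseline morbidity category: healthy, severity 0.
BASELINE_ACRG3 = "1-0"


def table1_probs() -> dict[str, float]:
    """Category probabilities from the published mix, normalized to sum 1.

    The printed cell percentages sum to 99.97 due to rounding; they are
    rescaled so the returned map is a proper probability distribution.
    """
    total = sum(TABLE1_PERCENT.values())
    return {k: v / total for k, v in TABLE1_PERCENT.items()}


def health_status(label: str) -> int:
    """Health status (1-9) encoded in an ACRG3 label ``"s-l"``."""
    return int(label.split("-")[0])


def severity_level(label: str) -> int:
    """Severity level (0-6) encoded in an ACRG3 label ``"s-l"``."""
    return int(label.split("-")[1])


def validate_label(label: str, catalog: tuple[str, ...] = ACRG3_CATALOG) -> str:
    if label not in catalog:
        raise ValueError(f"unknown ACRG3 label {label!r}")
    return label
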