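"""Published study-cohort bookkeeping used as fixed inputs.

These constants transcribe the recruitment/exclusion tallies and baseline
group means of the multicenter AMD cohort the pipeline is designed around
(control / early / intermediate / late AMD staging).  They are inputs for
consistency arithmetic — analyzed-eye counts, subgroup shares, and the
low-luminance-deficit identity — not outputs of this package.
"""

from __future__ import annotations

STAGES = ("no AMD", "early", "intermediate", "late")

#: recruited eyes and itemized exclusions per stage: participants lacking
#: complete functional data, and participants without rEZR determination at
#: the perimetry grid positions
RECRUITMENT = {
    "no AMD": {"recruited": 56, "excluded_functional": 2, "excluded_missing_rezr": 1},
    "early": {"recruited": 34, "excluded_functional": 0, "excluded_missing_rezr": 0},
    "intermediate": {"recruited": 168, "excluded_functional": 8, "excluded_missing_rezr": 8},
    "late": {"recruited": 43, "excluded_functional": 6, "excluded_missing_rezr": 1},
}

#: analyzed male counts per stage (baseline characteristics table)
MALE_COUNTS = {"no AMD": 22, "early": 7, "intermediate": 54, "late": 18}

#: analyzed group means of BCVA and LLVA (logMAR) per stage
CHART_MEANS = {
    "no AMD": {"bcva": -0.0404, "llva": 0.137},
    "early": {"bcva": 0.0106, "llva": 0.188},
    "intermediate": {"bcva": 0.0238, "llva": 0.237},
    "late": {"bcva": 0.763, "llva": 0.929},
}


def analyzed_counts() -> dict[str, int]:
    """Analyzed eyes per stage: recruited minus itemized exclusions."""
    return {
        s: r["recruited"] - r["excluded_functional"] - r["excluded_missing_rezr"]
        for s, r in RECRUITMENT.items()
    }


def cohort_bookkeeping() -> dict[str, float]:
    """Total analyzed eyes and subgroup shares (percent of analyzed)."""
    counts = analyzed_counts()
    total = sum(counts.values())
    male = sum(MALE_COUNTS.values())
    return {
        "recruited": sum(r["recruited"] for r in RECRUITMENT.values()),
        "excluded": sum(
            r["excluded_functional"] + r["excluded_missing_rezr"]
            for r in RECRUITMENT.values()
        ),
        "analyzed": total,
        **{f"share_{s}": 100.0 * counts[s] / total for s in STAGES},
        "share_female": 100.0 * (total - male) / total,
    }
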