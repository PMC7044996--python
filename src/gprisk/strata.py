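"""Population strata: gender by 5-year age band.

Registered-population tables are held in wide form with one column per
stratum, named ``{gender}_{band}`` (e.g. ``F_0-4``, ``M_85+``). GP ages use
coarser career bands for the retention lookup.
"""

from __future__ import annotations

AGE_BANDS: list[str] = [
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85+",
]

GENDERS: list[str] = ["F", "M"]

STRATA: list[str] = [f"{g}_{b}" for g in GENDERS for b in AGE_BANDS]

#: midpoint age of each band, 85+ treated as 87.5
AGE_MIDPOINTS: dict[str, float] = {
    b: (87.5 if b == "85+" else (float(b.split("-")[0]) + float(b.split("-")[1])) / 2.0)
    for b in AGE_BANDS
}

#: GP career age bands used by the retention survival lookup
GP_AGE_BANDS: list[str] = ["25-29", "30-34", "35-39", "40-44", "45-49",
                           "50-54", "55-59", "60-64", "65+"]


def gp_age_band(age: float) -> str:
    """Map a GP age in years to a career band, clamping outside 25-65+."""
    if age < 25:
        return "25-29"
    if age >= 65:
        return "65+"
    lo = int(age // 5) * 5
    return f"{lo}-{lo + 4}"


def stratum_age_band(stratum: str) -> str:
    return stratum.split("_", 1)[1]


def stratum_gender(stratum: str) -> str:
    return stratum.split("_", 1)[0]
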