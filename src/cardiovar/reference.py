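"""Published group-level hemodynamic reference values for control and HFrEF mice.

These are in-vivo left-ventricular catheterisation summaries (mean +/- SD across
animals) for a control group (n = 14) and a pharmacologically induced
heart-failure-with-reduced-ejection-fraction group (n = 10).  They serve two
purposes here: they are the moment targets the synthetic-cohort generator aims
at, and they are the worked-example inputs for consistency checks such as
SV = EDV - ESV holding for the group means.
"""

from __future__ import annotations

GROUP_N = {"control": 14, "hfref": 10}

# parameter -> (control mean, control SD, hfref mean, hfref SD)
GROUP_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "HR_bpm": (481.14, 44.74, 483.60, 37.22),
    "ESP_mmHg": (54.05, 12.22, 82.95, 18.75),
    "EDP_mmHg": (4.53, 2.25, 5.94, 2.77),
    "Pmax_mmHg": (60.93, 11.78, 92.60, 19.18),
    "Pmin_mmHg": (2.58, 2.10, 3.12, 1.73),
    "dPdt_max_mmHg_per_s": (4309.12, 973.09, 5702.65, 1391.61),
    "dPdt_min_mmHg_per_s": (-3829.84, 1270.54, -5546.37, 1610.70),
    "Vmax_ul": (41.28, 9.31, 27.82, 11.27),
    "Vmin_ul": (12.48, 5.75, 11.58, 4.98),
    "ESV_ul": (15.33, 6.45, 13.36, 5.46),
    "EDV_ul": (39.13, 9.04, 25.45, 9.46),
    "SV_ul": (23.80, 5.48, 12.09, 4.80),
    "CO_ul_per_min": (11471.31, 2879.14, 5894.72, 2373.94),
    "EF_pct": (61.74, 11.76, 46.97, 10.05),
}


def group_mean(parameter: str, group: str) -> float:
    """Return the published group mean of one hemodynamic parameter."""
    row = GROUP_SUMMARY[parameter]
    if group == "control":
        return row[0]
    if group == "hfref":
        return row[2]
    raise KeyError(f"unknown group {group!r}")


def group_sd(parameter: str, group: str) -> float:
    """Return the published between-animal SD of one hemodynamic parameter."""
    row = GROUP_SUMMARY[parameter]
    if group == "control":
        return row[1]
    if group == "hfref":
        return row[3]
    raise KeyError(f"unknown group {group!r}")
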