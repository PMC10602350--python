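"""Seeded synthetic cohorts of murine beat series and rendered PV recordings.

The generator emulates two phenotypes — healthy controls and heart failure
with reduced ejection fraction (HFrEF) — at the level the downstream analyses
consume: per-cycle series of cycle duration and stroke volume, and smooth
pressure-volume waveforms carrying the per-cycle landmarks (EDV, ESV, EDP,
ESP, Pmax, Pmin).  Ground truth is kept alongside every artefact so that
extraction and variability stages can be validated by round-trip.

Generative law (per animal): cycle durations are i.i.d. Gaussian around the
animal's mean with SD ``hrv_sd`` (floored at 20% of the mean); stroke volumes
follow a stationary AR(1) with mean ``mean_sv``, stationary SD ``svv_sd`` and
lag-1 autocorrelation ``sv_lag1_autocorr`` (floored at 0.1 μl).  The AR(1)
choice mirrors the affine stroke-volume recursion of the two-compartment
circulation model (:mod:`cardiovar.frank_starling`), which is the stationary
law that model implies.

Waveform morphology is a fixed piecewise raised-cosine template per cycle —
isovolumic contraction, ejection, isovolumic relaxation, filling — chosen so
every landmark is attained exactly and the concatenated trace is continuous.
Only per-cycle summary parameters feed the analyses, so the template shape
itself is not a scientific claim.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import reference
from .hemodynamics import PVRecord, write_pv_csv

__all__ = [
    "PhenotypeSpec",
    "CohortSpec",
    "Animal",
    "Cohort",
    "CONTROL_PHENOTYPE",
    "HFREF_PHENOTYPE",
    "default_cohort_spec",
    "generate_beat_series",
    "render_pv_record",
    "generate_cohort",
    "write_cohort",
]

# fractions of the cycle devoted to each phase of the waveform template
_F_EDP = 0.02    # end-diastolic pressure plateau (sub-sample boundary tolerance)
_F_IVC = 0.12    # isovolumic contraction ends
_F_EJ = 0.40     # ejection ends (end systole)
_F_PMIN = 0.50   # relaxation pressure fall reaches Pmin
_F_IVR = 0.52    # isovolumic relaxation ends; filling occupies the rest
_F_PEAK = 0.55   # position of the pressure peak within ejection
_P_OPEN_FRAC = 0.55  # fraction of (Pmax - EDP) reached when ejection starts

_RHO_SIZE = 0.3  # loading of EDV on the shared heart-size factor (with SV)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Target moments of one group's beat-to-beat physiology.

    Means are within-animal expectations; ``hrv_sd`` and ``svv_sd`` are
    within-animal beat-to-beat SDs; ``between_animal_cv`` disperses the
    per-animal means around these group targets.
    """

    mean_cycle_duration: float   # ms
    hrv_sd: float                # ms
    mean_sv: float               # μl
    svv_sd: float                # μl
    sv_lag1_autocorr: float      # (-1, 1)
    mean_edp: float              # mmHg
    mean_esp: float              # mmHg
    mean_pmax: float             # mmHg
    mean_pmin: float             # mmHg
    mean_edv: float              # μl
    between_animal_cv: float     # fraction

    def __post_init__(self) -> None:
        if self.mean_cycle_duration <= 0 or self.mean_sv <= 0:
            raise ValueError("mean cycle duration and mean SV must be positive")
        if self.mean_edv <= self.mean_sv:
            raise ValueError("mean_edv must exceed mean_sv (ESV would be <= 0)")
        if self.hrv_sd < 0 or self.svv_sd < 0 or self.between_animal_cv < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if not abs(self.sv_lag1_autocorr) < 1:
            raise ValueError("|sv_lag1_autocorr| must be < 1")
        if not (0 <= self.mean_pmin <= self.mean_edp <= self.mean_esp <= self.mean_pmax):
            raise ValueError("pressures must satisfy 0 <= Pmin <= EDP <= ESP <= Pmax")


def _phenotype_from_reference(group: str, hrv_sd: float, svv_sd: float,
                              lag1: float, cv: float) -> PhenotypeSpec:
    g = lambda p: reference.group_mean(p, group)  # noqa: E731
    return PhenotypeSpec(
        mean_cycle_duration=60000.0 / g("HR_bpm"),
        hrv_sd=hrv_sd,
        mean_sv=g("SV_ul"),
        svv_sd=svv_sd,
        sv_lag1_autocorr=lag1,
        mean_edp=g("EDP_mmHg"),
        mean_esp=g("ESP_mmHg"),
        mean_pmax=g("Pmax_mmHg"),
        mean_pmin=g("Pmin_mmHg"),
        mean_edv=g("EDV_ul"),
        between_animal_cv=cv,
    )


# Default study conditions.  Group means come from the published murine
# reference values; within-animal variability levels are free parameters of
# the generator (no published within-animal SDs exist): HRV is equal across
# groups (preserved in HFrEF), while the HFrEF stroke-volume SD is halved
# (SVV reduced).  See docs/methods.md.
CONTROL_PHENOTYPE = _phenotype_from_reference(
    "control", hrv_sd=3.0, svv_sd=1.2, lag1=0.5, cv=0.15)
HFREF_PHENOTYPE = _phenotype_from_reference(
    "hfref", hrv_sd=3.0, svv_sd=0.6, lag1=0.5, cv=0.15)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a two-group synthetic cohort."""

    n_control: int = 14
    n_hfref: int = 10
    control: PhenotypeSpec = CONTROL_PHENOTYPE
    hfref: PhenotypeSpec = HFREF_PHENOTYPE
    n_cycles_per_animal: int = 2000  # ~4 min of recording at murine heart rates
    sampling_rate: float = 1000.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_hfref < 2:
            raise ValueError("need at least 2 animals per group")
        if self.n_cycles_per_animal < 3:
            raise ValueError("need at least 3 cycles per animal")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        raw = json.loads(Path(path).read_text())
        for key in ("control", "hfref"):
            if isinstance(raw.get(key), dict):
                raw[key] = PhenotypeSpec(**raw[key])
        return cls(**raw)


def default_cohort_spec(master_seed: int = 0, **overrides) -> CohortSpec:
    return replace(CohortSpec(master_seed=master_seed), **overrides)


def generate_beat_series(
    phenotype: PhenotypeSpec,
    n_cycles: int,
    seed: int,
    duration_floor_frac: float = 0.2,
    sv_floor_ul: float = 0.1,
) -> pd.DataFrame:
    """Paired per-cycle series of duration (ms) and stroke volume (μl).

    Durations are i.i.d. Gaussian, floored at ``duration_floor_frac`` of the
    mean; stroke volumes follow a stationary AR(1) started from its stationary
    law and floored at ``sv_floor_ul``.  Identical seeds give identical output.
    """
    if n_cycles <= 0:
        raise ValueError("n_cycles must be positive")
    rng = np.random.default_rng(seed)

    mu_t = phenotype.mean_cycle_duration
    durations = rng.normal(mu_t, phenotype.hrv_sd, size=n_cycles)
    np.clip(durations, duration_floor_frac * mu_t, None, out=durations)

    phi = phenotype.sv_lag1_autocorr
    mu, sd = phenotype.mean_sv, phenotype.svv_sd
    if sd == 0:
        sv = np.full(n_cycles, mu)
    else:
        x0 = rng.normal(0.0, sd)
        eps = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n_cycles - 1)
        zi = signal.lfiltic([1.0], [1.0, -phi], [x0])
        rest, _ = signal.lfilter([1.0], [1.0, -phi], eps, zi=zi)
        sv = mu + np.concatenate([[x0], rest])
        np.clip(sv, sv_floor_ul, None, out=sv)
    return pd.DataFrame({"duration_ms": durations, "sv_ul": sv})


def _raised_cosine(s: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * s))


def render_pv_record(
    beats: pd.DataFrame,
    phenotype: PhenotypeSpec,
    sampling_rate: float,
) -> tuple[PVRecord, pd.DataFrame]:
    """Render a beat series into a continuous PV waveform plus ground truth.

    Each cycle runs end diastole to end diastole through four raised-cosine
    phases.  Volume: plateau at EDV (isovolumic contraction), fall to
    ESV = EDV - SV (ejection), plateau at ESV (isovolumic relaxation), refill
    to EDV.  Pressure: rise EDP -> opening pressure, bump to Pmax then decay
    to ESP across ejection, fast fall to Pmin (so the dP/dt minimum lands in
    the ESV plateau), slow recovery to EDP across filling.

    Returns the record and a per-cycle ground-truth table.
    """
    if len(beats) == 0:
        raise ValueError("beat series is empty")
    if sampling_rate < 1000.0:
        raise ValueError("sampling_rate must be >= 1000 Hz to resolve murine cycles")
    durations_s = beats["duration_ms"].to_numpy(dtype=float) / 1000.0
    sv = beats["sv_ul"].to_numpy(dtype=float)
    if np.min(durations_s) * sampling_rate < 50:
        raise ValueError("sampling too coarse to place cycle landmarks distinctly")

    edv = phenotype.mean_edv
    esv = edv - sv
    if np.any(esv <= 0):
        raise ValueError("stroke volume exceeds EDV: negative end-systolic volume")
    edp, esp = phenotype.mean_edp, phenotype.mean_esp
    pmax, pmin = phenotype.mean_pmax, phenotype.mean_pmin
    p_open = edp + _P_OPEN_FRAC * (pmax - edp)

    ends = np.cumsum(durations_s)
    n = int(math.floor(ends[-1] * sampling_rate))
    t = np.arange(n) / sampling_rate
    ci = np.searchsorted(ends, t, side="right")
    t0 = ends[ci] - durations_s[ci]
    u = (t - t0) / durations_s[ci]

    sv_c, esv_c = sv[ci], esv[ci]
    pressure = np.empty(n)
    volume = np.empty(n)

    m1 = u < _F_IVC
    m2 = (~m1) & (u < _F_EJ)
    m3 = (~m1) & (~m2) & (u < _F_IVR)
    m4 = u >= _F_IVR

    volume[m1] = edv
    s2 = (u[m2] - _F_IVC) / (_F_EJ - _F_IVC)
    volume[m2] = edv - sv_c[m2] * _raised_cosine(s2)
    volume[m3] = esv_c[m3]
    s4 = (u[m4] - _F_IVR) / (1.0 - _F_IVR)
    volume[m4] = esv_c[m4] + sv_c[m4] * _raised_cosine(s4)

    s1 = np.clip((u[m1] - _F_EDP) / (_F_IVC - _F_EDP), 0.0, None)
    pressure[m1] = edp + (p_open - edp) * _raised_cosine(s1)
    rising = s2 < _F_PEAK
    p2 = np.empty(s2.size)
    p2[rising] = p_open + (pmax - p_open) * _raised_cosine(s2[rising] / _F_PEAK)
    p2[~rising] = pmax - (pmax - esp) * _raised_cosine(
        (s2[~rising] - _F_PEAK) / (1.0 - _F_PEAK))
    pressure[m2] = p2
    # smooth fall so every dP/dt landmark sits at a well-resolved interior
    # extremum; the dP/dt minimum lands mid-relaxation, on the ESV plateau,
    # and Pmin is held briefly so its sampled value is exact
    s3 = np.clip((u[m3] - _F_EJ) / (_F_PMIN - _F_EJ), 0.0, 1.0)
    pressure[m3] = esp - (esp - pmin) * _raised_cosine(s3)
    pressure[m4] = pmin + (edp - pmin) * _raised_cosine(s4)

    record = PVRecord(time=t, pressure=pressure, volume=volume, sampling_rate=sampling_rate)
    truth = pd.DataFrame({
        "cycle": np.arange(len(beats)),
        "t_start_s": ends - durations_s,
        "duration_ms": durations_s * 1000.0,
        "sv_ul": sv,
        "edv_ul": np.full(len(beats), edv),
        "esv_ul": esv,
        "edp_mmHg": np.full(len(beats), edp),
        "esp_mmHg": np.full(len(beats), esp),
        "pmax_mmHg": np.full(len(beats), pmax),
        "pmin_mmHg": np.full(len(beats), pmin),
    })
    return record, truth


@dataclass
class Animal:
    animal_id: str
    group: str
    seed: int
    phenotype: PhenotypeSpec
    beats: pd.DataFrame                 # ground-truth per-cycle duration & SV
    record: PVRecord | None = None
    truth: pd.DataFrame | None = None   # per-cycle waveform landmarks


@dataclass
class Cohort:
    spec: CohortSpec
    animals: list[Animal]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"animal_id": a.animal_id, "group": a.group,
              "file": f"{a.animal_id}.csv", "seed": a.seed,
              "sampling_rate_hz": self.spec.sampling_rate}
             for a in self.animals]
        )

    def by_group(self, group: str) -> list[Animal]:
        return [a for a in self.animals if a.group == group]


def _animal_seeds(master_seed: int, group_code: int, index: int) -> tuple[int, int]:
    """Deterministic (phenotype_seed, beat_seed) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), group_code, index])
    a, b = ss.generate_state(2)
    return int(a & 0x7FFFFFFF), int(b & 0x7FFFFFFF)


def _draw_animal_phenotype(base: PhenotypeSpec, rng: np.random.Generator) -> PhenotypeSpec:
    """Per-animal phenotype around the group targets with CV ``between_animal_cv``.

    A shared size factor couples SV and EDV (loading ``_RHO_SIZE``) so ejection
    fraction varies while EDV > SV is preserved; all four pressure means share
    one scale factor so their physiological ordering is exact; within-animal
    SDs (hrv_sd, svv_sd) receive their own dispersion.
    """
    cv = base.between_animal_cv
    z_size, z_edv, z_p, z_t, z_h, z_s = rng.normal(size=6)
    sv = base.mean_sv * (1.0 + cv * z_size)
    edv = base.mean_edv * (
        1.0 + cv * (_RHO_SIZE * z_size + math.sqrt(1.0 - _RHO_SIZE**2) * z_edv))
    edv = max(edv, 0.2 * base.mean_edv)
    # keep ~6 SD of beat-to-beat SV fluctuation below EDV so rendered cycles
    # always have positive end-systolic volume
    svv_sd = min(base.svv_sd * max(0.0, 1.0 + cv * z_s), edv / 12.0)
    sv = float(np.clip(sv, 0.15 * edv, min(0.85 * edv, edv - 6.0 * svv_sd)))
    f_p = max(0.3, 1.0 + cv * z_p)
    return PhenotypeSpec(
        mean_cycle_duration=max(0.5 * base.mean_cycle_duration,
                                base.mean_cycle_duration * (1.0 + cv * z_t)),
        hrv_sd=base.hrv_sd * max(0.0, 1.0 + cv * z_h),
        mean_sv=sv,
        svv_sd=svv_sd,
        sv_lag1_autocorr=base.sv_lag1_autocorr,
        mean_edp=base.mean_edp * f_p,
        mean_esp=base.mean_esp * f_p,
        mean_pmax=base.mean_pmax * f_p,
        mean_pmin=base.mean_pmin * f_p,
        mean_edv=edv,
        between_animal_cv=0.0,
    )


def generate_cohort(spec: CohortSpec, render: bool = True) -> Cohort:
    """Generate the full two-group cohort (deterministic in ``master_seed``).

    With ``render=True`` every animal also carries a rendered PV record and
    its per-cycle waveform ground truth; ``render=False`` keeps only the beat
    series (cheaper, sufficient for variability/statistics studies).
    """
    animals: list[Animal] = []
    for group_code, (group, base, n) in enumerate(
        [("control", spec.control, spec.n_control), ("hfref", spec.hfref, spec.n_hfref)]
    ):
        for i in range(n):
            pheno_seed, beat_seed = _animal_seeds(spec.master_seed, group_code, i)
            phenotype = _draw_animal_phenotype(base, np.random.default_rng(pheno_seed))
            beats = generate_beat_series(phenotype, spec.n_cycles_per_animal, beat_seed)
            record = truth = None
            if render:
                record, truth = render_pv_record(beats, phenotype, spec.sampling_rate)
            animals.append(Animal(
                animal_id=f"{group}_{i:02d}", group=group, seed=beat_seed,
                phenotype=phenotype, beats=beats, record=record, truth=truth,
            ))
    return Cohort(spec=spec, animals=animals)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-animal PV CSVs, the manifest, ground truth and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for a in cohort.animals:
        if a.record is None:
            raise ValueError(f"{a.animal_id}: cohort was generated without rendering")
        write_pv_csv(a.record, outdir / f"{a.animal_id}.csv")
    cohort.manifest().to_csv(outdir / "manifest.csv", index=False)
    truth_frames = []
    for a in cohort.animals:
        t = (a.truth if a.truth is not None else a.beats).copy()
        t.insert(0, "animal_id", a.animal_id)
        truth_frames.append(t)
    pd.concat(truth_frames, ignore_index=True).to_csv(outdir / "ground_truth.csv", index=False)
    cohort.spec.to_json(outdir / "cohort_config.json")
    return outdir
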