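"""Synthetic 1H-NMR serum cohort generator.

Forward model for a one-dimensional spectrum: each metabolite contributes a
set of resonances, each rendered as a Lorentzian multiplet whose integrated
area is proportional to the metabolite's concentration. A cohort is a set of
groups whose group-mean concentrations differ by prescribed fold changes,
with per-sample log-normal biological variation, a global per-sample
dilution factor (to exercise quotient normalization downstream), a
slow sinusoidal baseline and additive Gaussian noise.

Multiplet conventions (the source tables give only multiplicity codes, so a
fixed rendering is adopted): s = 1 line; d = 2 equal lines split by J;
t = 3 lines 1:2:1; q = 4 lines 1:3:3:1; dd = 4 equal lines split by J and
0.4 J; m and br = a single Lorentzian broadened to 3x the nominal
linewidth. J is fixed at 7 Hz and converted to ppm at the 599.808 MHz
proton frequency of the instrument being emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._names import normalize_name
from .data import RESONANCES, fixture_path
from .preprocess import Spectrum

J_COUPLING_HZ = 7.0
SPECTROMETER_MHZ = 599.808
J_COUPLING_PPM = J_COUPLING_HZ / SPECTROMETER_MHZ

#: (offset in units of J, fractional area) per line of each multiplet code
MULTIPLET_PATTERNS: dict[str, tuple[tuple[float, float], ...]] = {
    "s": ((0.0, 1.0),),
    "d": ((-0.5, 0.5), (0.5, 0.5)),
    "t": ((-1.0, 0.25), (0.0, 0.5), (1.0, 0.25)),
    "q": ((-1.5, 0.125), (-0.5, 0.375), (0.5, 0.375), (1.5, 0.125)),
    "dd": ((-0.7, 0.25), (-0.3, 0.25), (0.3, 0.25), (0.7, 0.25)),
    "m": ((0.0, 1.0),),
    "br": ((0.0, 1.0),),
}
#: codes rendered as a single line broadened to 3x the nominal linewidth
BROADENED_CODES = frozenset({"m", "br"})


@dataclass(frozen=True)
class Resonance:
    shift: float  # ppm
    multiplicity: str
    relative_area: float


@dataclass
class MetaboliteSpec:
    """One metabolite's resonances and its reference-group concentration."""

    name: str
    resonances: list[Resonance]
    base_level: float = 1.0
    integration_shift: float | None = None  # ppm; default: first resonance

    def __post_init__(self) -> None:
        if not self.resonances:
            raise ValueError(f"{self.name}: at least one resonance required")
        if self.base_level <= 0:
            raise ValueError(f"{self.name}: base_level must be > 0")
        for r in self.resonances:
            if r.multiplicity not in MULTIPLET_PATTERNS:
                raise ValueError(
                    f"{self.name}: unknown multiplicity code {r.multiplicity!r}"
                )
            if not 0.0 <= r.shift <= 10.0:
                raise ValueError(f"{self.name}: shift {r.shift} outside 0-10 ppm")
        total = sum(r.relative_area for r in self.resonances)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"{self.name}: relative areas sum to {total}, not 1")
        # snap tiny rounding in the fixture to an exact partition
        self.resonances = [
            replace(r, relative_area=r.relative_area / total) for r in self.resonances
        ]

    @property
    def window_center(self) -> float:
        return (
            self.integration_shift
            if self.integration_shift is not None
            else self.resonances[0].shift
        )


@dataclass
class EffectTable:
    """Fold changes per (metabolite, contrast); contrast labels are
    ``CASE_vs_REFERENCE`` over cohort group names."""

    frame: pd.DataFrame  # columns: metabolite, contrast, fold_change

    def __post_init__(self) -> None:
        required = {"metabolite", "contrast", "fold_change"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"effect table needs columns {sorted(required)}")
        if (self.frame["fold_change"] <= 0).any():
            raise ValueError("fold changes must be > 0")
        if self.frame.duplicated(["metabolite", "contrast"]).any():
            raise ValueError("one row per (metabolite, contrast) required")

    @classmethod
    def empty(cls) -> "EffectTable":
        return cls(pd.DataFrame(columns=["metabolite", "contrast", "fold_change"]))


@dataclass
class CohortDesign:
    groups: tuple[str, ...] = ("WKY-N", "SHR-N")
    n_per_group: int = 10
    dilution_sd: float = 0.1  # log-scale sd of the per-sample global factor
    noise_sd: float = 0.5  # additive noise, intensity units
    baseline_amplitude: float = 0.5  # slow sinusoid, intensity units
    linewidth: float = 0.002  # Lorentzian half width at half maximum, ppm
    ppm_min: float = 0.5
    ppm_max: float = 9.0
    n_points: int = 16384
    biological_cv: float = 0.10  # per-sample log-normal level variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.n_points < 1000:
            raise ValueError("n_points must be >= 1000")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        if self.ppm_min >= self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")

    def ppm_grid(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


@dataclass
class SpectrumSet:
    spectra: list[Spectrum]
    design: CohortDesign
    truth: EffectTable
    #: per-sample nuisance truth (dilution factor) for recovery tests
    sample_truth: pd.DataFrame | None = None

    @property
    def sample_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": [s.sample_id for s in self.spectra],
             "group": [s.group for s in self.spectra]}
        )


def load_resonance_library(path: str | Path | None = None) -> list[MetaboliteSpec]:
    """Load MetaboliteSpecs from a resonance-library CSV.

    The packaged default covers every metabolite in the two transcribed
    biomarker tables. Raises ``ValueError`` (naming the offending row) on
    unknown multiplicity codes or non-numeric shifts.
    """
    path = fixture_path(RESONANCES) if path is None else Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: resonance library is empty")
    required = {"metabolite", "shift_ppm", "multiplicity"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    specs: list[MetaboliteSpec] = []
    for name, rows in frame.groupby("metabolite", sort=False):
        resonances = []
        for idx, row in rows.iterrows():
            mult = str(row["multiplicity"]).strip()
            if mult not in MULTIPLET_PATTERNS:
                raise ValueError(
                    f"{path} row {idx + 2}: unknown multiplicity code {mult!r} "
                    f"for metabolite {name!r}"
                )
            shift = float(row["shift_ppm"])
            area = float(row.get("relative_area", np.nan))
            if np.isnan(area):
                area = 1.0 / len(rows)
            resonances.append(Resonance(shift, mult, area))
        base = float(rows["base_level"].iloc[0]) if "base_level" in rows else 1.0
        integ = None
        if "integration_shift" in rows and not pd.isna(rows["integration_shift"].iloc[0]):
            integ = float(rows["integration_shift"].iloc[0])
        specs.append(MetaboliteSpec(str(name), resonances, base, integ))
    return specs


def load_effect_table(
    path: str | Path, contrast: str, fc_column: str = "fc"
) -> EffectTable:
    """Build an EffectTable from a biomarker-table CSV's fold-change column."""
    frame = pd.read_csv(path)
    return EffectTable(
        pd.DataFrame(
            {
                "metabolite": frame["metabolite"].astype(str),
                "contrast": contrast,
                "fold_change": frame[fc_column].astype(float),
            }
        )
    )


def _lorentzian(ppm: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line."""
    return (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)


def render_profile(
    specs: Sequence[MetaboliteSpec],
    levels: Mapping[str, float],
    ppm: np.ndarray,
    linewidth: float,
) -> np.ndarray:
    """Noiseless spectrum: sum of concentration-weighted multiplets.

    Linear in the concentration vector; each metabolite's total integrated
    area equals its level.
    """
    out = np.zeros_like(ppm)
    for spec in specs:
        level = float(levels.get(spec.name, 0.0))
        if level < 0:
            raise ValueError(f"{spec.name}: negative level")
        if level == 0.0:
            continue
        for res in spec.resonances:
            hwhm = linewidth * (3.0 if res.multiplicity in BROADENED_CODES else 1.0)
            for offset, frac in MULTIPLET_PATTERNS[res.multiplicity]:
                center = res.shift + offset * J_COUPLING_PPM
                out += (level * res.relative_area * frac) * _lorentzian(
                    ppm, center, hwhm
                )
    return out


def simulate_spectrum(
    specs: Sequence[MetaboliteSpec],
    levels: Mapping[str, float],
    design: CohortDesign,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    group: str | None = None,
    dilution: float | None = None,
) -> Spectrum:
    """One spectrum: dilution x rendered profile + baseline + noise."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    ppm = design.ppm_grid()
    if np.any(np.diff(ppm) <= 0):
        raise ValueError("ppm grid must be strictly increasing")
    intensity = render_profile(specs, levels, ppm, design.linewidth)
    if dilution is None:
        dilution = (
            float(np.exp(rng.normal(0.0, design.dilution_sd)))
            if design.dilution_sd > 0
            else 1.0
        )
    intensity = intensity * dilution
    if design.baseline_amplitude > 0:
        cycles = int(rng.integers(1, 4))
        phase = float(rng.uniform(0, 2 * np.pi))
        x = (ppm - design.ppm_min) / (design.ppm_max - design.ppm_min)
        intensity = intensity + design.baseline_amplitude * np.sin(
            2 * np.pi * cycles * x + phase
        )
    if design.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, design.noise_sd, ppm.size)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("non-finite intensities produced")
    return Spectrum(ppm=ppm, intensity=intensity, sample_id=sample_id, group=group)


def _parse_contrasts(
    effects: EffectTable, groups: Sequence[str]
) -> dict[str, tuple[str, dict[str, float]]]:
    """Map each case group to (reference group, {metabolite: fc})."""
    out: dict[str, tuple[str, dict[str, float]]] = {}
    for contrast, rows in effects.frame.groupby("contrast"):
        if "_vs_" not in str(contrast):
            raise ValueError(f"contrast {contrast!r} is not of the form CASE_vs_REF")
        case, ref = str(contrast).split("_vs_", 1)
        for g in (case, ref):
            if g not in groups:
                raise ValueError(f"contrast {contrast!r} references unknown group {g!r}")
        if case in out and out[case][0] != ref:
            raise ValueError(f"group {case!r} has conflicting reference groups")
        out[case] = (ref, dict(zip(rows["metabolite"], rows["fold_change"])))
    return out


def group_mean_levels(
    specs: Sequence[MetaboliteSpec],
    effects: EffectTable,
    groups: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Resolve per-group mean concentrations from chained fold changes.

    The first group is the reference and uses base levels; any group named
    as a case in a contrast gets its reference's levels scaled by the fold
    changes, so a treatment contrast defined against the disease group
    composes with the disease contrast automatically.
    """
    canonical = {normalize_name(s.name): s.name for s in specs}
    missing = [
        m for m in effects.frame["metabolite"] if normalize_name(m) not in canonical
    ]
    if missing:
        raise ValueError(f"effect metabolites not in resonance library: {sorted(set(missing))}")
    contrasts = _parse_contrasts(effects, groups)
    contrasts = {
        case: (ref, {canonical[normalize_name(m)]: v for m, v in fcs.items()})
        for case, (ref, fcs) in contrasts.items()
    }
    base = {s.name: s.base_level for s in specs}
    levels: dict[str, dict[str, float]] = {}

    def resolve(group: str, seen: frozenset[str]) -> dict[str, float]:
        if group in levels:
            return levels[group]
        if group in seen:
            raise ValueError(f"cyclic contrast chain at group {group!r}")
        if group == groups[0] or group not in contrasts:
            levels[group] = dict(base)
            return levels[group]
        ref, fcs = contrasts[group]
        parent = resolve(ref, seen | {group})
        levels[group] = {m: parent[m] * fcs.get(m, 1.0) for m in parent}
        return levels[group]

    for g in groups:
        resolve(g, frozenset())
    return levels


def simulate_cohort(
    specs: Sequence[MetaboliteSpec],
    effects: EffectTable,
    design: CohortDesign,
) -> SpectrumSet:
    """Deterministic multi-group cohort; same design (incl. seed) gives a
    bit-identical SpectrumSet."""
    rng = np.random.default_rng(design.seed)
    means = group_mean_levels(specs, effects, design.groups)
    cv = design.biological_cv
    # mean-preserving log-normal: E[exp(N(-s^2/2, s))] = 1
    sigma = float(np.sqrt(np.log1p(cv**2))) if cv > 0 else 0.0
    spectra: list[Spectrum] = []
    dilutions: list[float] = []
    for group in design.groups:
        for i in range(design.n_per_group):
            if sigma > 0:
                jitter = np.exp(rng.normal(-sigma**2 / 2, sigma, len(specs)))
            else:
                jitter = np.ones(len(specs))
            sample_levels = {
                s.name: means[group][s.name] * jitter[k] for k, s in enumerate(specs)
            }
            dilution = (
                float(np.exp(rng.normal(0.0, design.dilution_sd)))
                if design.dilution_sd > 0
                else 1.0
            )
            dilutions.append(dilution)
            spectra.append(
                simulate_spectrum(
                    specs,
                    sample_levels,
                    design,
                    rng=rng,
                    sample_id=f"{group}-{i + 1:02d}",
                    group=group,
                    dilution=dilution,
                )
            )
    sample_truth = pd.DataFrame(
        {"group": [s.group for s in spectra], "dilution": dilutions},
        index=pd.Index([s.sample_id for s in spectra], name="sample_id"),
    )
    return SpectrumSet(spectra=spectra, design=design, truth=effects,
                       sample_truth=sample_truth)


# ---------------------------------------------------------------------------
# wide-CSV persistence: rows = samples, columns = ppm grid

def write_spectrum_set(sset: SpectrumSet, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ppm = sset.spectra[0].ppm
    data = pd.DataFrame(
        np.vstack([s.intensity for s in sset.spectra]),
        index=pd.Index([s.sample_id for s in sset.spectra], name="sample_id"),
        columns=[f"{p:.17g}" for p in ppm],
    )
    paths = {
        "spectra": out / "spectra.csv",
        "samples": out / "samples.csv",
        "design": out / "design.json",
    }
    data.to_csv(paths["spectra"], float_format="%.17g")
    sset.sample_meta.to_csv(paths["samples"], index=False)
    payload = {
        "design": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(sset.design).items()},
        "truth": sset.truth.frame.to_dict(orient="list"),
    }
    paths["design"].write_text(json.dumps(payload, indent=1))
    return paths


def read_spectrum_set(in_dir: str | Path) -> SpectrumSet:
    src = Path(in_dir)
    data = pd.read_csv(src / "spectra.csv", index_col="sample_id",
                       float_precision="round_trip")
    meta = pd.read_csv(src / "samples.csv")
    groups = dict(zip(meta["sample_id"], meta["group"]))
    ppm = np.array([float(c) for c in data.columns])
    spectra = [
        Spectrum(ppm=ppm, intensity=row.to_numpy(float), sample_id=str(sid),
                 group=groups.get(str(sid)))
        for sid, row in data.iterrows()
    ]
    payload = json.loads((src / "design.json").read_text())
    d = payload["design"]
    d["groups"] = tuple(d["groups"])
    design = CohortDesign(**d)
    truth = EffectTable(pd.DataFrame(payload["truth"])) if payload["truth"]["metabolite"] else EffectTable.empty()
    return SpectrumSet(spectra=spectra, design=design, truth=truth)
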