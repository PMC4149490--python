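"""Synthetic cytometry event generator.

Generates per-well event tables with the statistical structure the gating
and screening analysis assumes: a mixture of cell populations, per-antigen
positive fractions, log-normal fluorescence (autofluorescence plus a
stained component), linear spillover between detectors, DAPI-bright dead
cells, pulse-geometry doublets, and well-level technical jitter.  A
treatment specification perturbs per-antigen detectability before
simulation, planting ground truth for screen-recovery tests.

All fluorescence is simulated in linear scale as sums of log-normal
components, so values are strictly positive and the positive/negative
bimodality that FMO gating relies on emerges directly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Antibody, ControlWell, PanelPlateMap

__all__ = [
    "PopulationSpec",
    "SpilloverMatrix",
    "TechnicalNoiseModel",
    "TreatmentEffectSpec",
    "EventTable",
    "simulate_well",
    "simulate_screen_plate",
    "well_seed",
    "SCATTER_CHANNELS",
    "VIABILITY_CHANNEL",
]

SCATTER_CHANNELS = ["FSC-A", "FSC-H", "FSC-W", "SSC-A"]
VIABILITY_CHANNEL = "DAPI-A"

# Pulse-geometry scatter modes (log10 of arbitrary linear units).
_FSC_A = (5.0, 0.06)
_FSC_H = (4.9, 0.06)
_FSC_W = (1.85, 0.02)
_SSC_A = (4.5, 0.12)
# Viability dye uptake by dead cells: >= 10x the live-mode median.
_DEAD_STAIN = (3.6, 0.15)


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population in the simulated mixture.

    ``positive_fraction`` gives, per antigen, the fraction of this
    population's cells that express the antigen (and hence acquire the
    stained signal when the matching antibody is in the well).
    ``stain_intensity`` optionally overrides the stained-signal log-normal
    per antigen; ``autofluorescence`` is the unstained background applied
    to every fluorescence channel (per-channel overrides allowed).
    """

    name: str
    abundance: float
    positive_fraction: Mapping[str, float] = field(default_factory=dict)
    stain_intensity: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    autofluorescence: tuple[float, float] = (2.0, 0.25)
    autofluorescence_per_channel: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    default_stain_intensity: tuple[float, float] = (3.5, 0.30)

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError(f"abundance {self.abundance} outside [0,1]")
        for ag, f in self.positive_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"positive_fraction[{ag!r}]={f} outside [0,1]")
        for m, s in [self.autofluorescence, self.default_stain_intensity]:
            if s <= 0:
                raise ValueError("log10 sd must be > 0")

    def af_params(self, channel: str) -> tuple[float, float]:
        return self.autofluorescence_per_channel.get(channel, self.autofluorescence)

    def stain_params(self, antigen: str) -> tuple[float, float]:
        return self.stain_intensity.get(antigen, self.default_stain_intensity)


@dataclass(frozen=True)
class SpilloverMatrix:
    """Linear spillover: entry (i, j) = fraction of channel-i signal read in j."""

    channels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if v.shape != (n, n):
            raise ValueError(f"spillover must be {n}x{n}, got {v.shape}")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("spillover diagonal must be 1")
        off = v[~np.eye(n, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("off-diagonal spillover must lie in [0, 1)")
        if abs(np.linalg.det(v)) < 1e-12:
            raise ValueError("spillover matrix is singular")
        object.__setattr__(self, "values", v)

    @classmethod
    def identity(cls, channels: Sequence[str]) -> "SpilloverMatrix":
        return cls(tuple(channels), np.eye(len(channels)))

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.values)


def default_spillover() -> SpilloverMatrix:
    """Mild PE/FITC/APC cross-talk typical of a 3-colour panel."""
    channels = ("PE-A", "FITC-A", "APC-A")
    v = np.array(
        [
            [1.00, 0.04, 0.01],
            [0.06, 1.00, 0.00],
            [0.01, 0.00, 1.00],
        ]
    )
    return SpilloverMatrix(channels, v)


@dataclass(frozen=True)
class TechnicalNoiseModel:
    """Per-well acquisition noise: event depth, dead/doublet rates, spillover,
    and a log10 intensity jitter applied once per well (run-to-run drift)."""

    events_per_well: int = 10_000
    dead_fraction: float = 0.05
    doublet_fraction: float = 0.03
    spillover: SpilloverMatrix | None = None
    intensity_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.events_per_well < 1:
            raise ValueError("events_per_well must be >= 1")
        for name in ("dead_fraction", "doublet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.intensity_jitter_sd < 0:
            raise ValueError("intensity_jitter_sd must be >= 0")


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Per-antigen perturbation of detectability by a preparation step.

    ``effects`` maps antigen -> ("set", new_fraction) or ("scale", factor);
    results are clipped to [0, 1] when applied.
    """

    label: str
    effects: Mapping[str, tuple[str, float]] = field(default_factory=dict)

    def apply(self, populations: Sequence[PopulationSpec]) -> list[PopulationSpec]:
        out = []
        for pop in populations:
            pf = dict(pop.positive_fraction)
            for antigen, (mode, value) in self.effects.items():
                if antigen not in pf and mode == "set":
                    pf[antigen] = 0.0
                if antigen not in pf:
                    continue
                if mode == "set":
                    pf[antigen] = value
                elif mode == "scale":
                    pf[antigen] = pf[antigen] * value
                else:
                    raise ValueError(f"unknown effect mode {mode!r}")
                pf[antigen] = float(np.clip(pf[antigen], 0.0, 1.0))
            out.append(replace(pop, positive_fraction=pf))
        return out


@dataclass
class EventTable:
    """Per-well event x channel matrix plus acquisition metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("EventTable needs >= 1 event")
        if self.data.columns.duplicated().any():
            raise ValueError("channel names must be unique")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("event values must be finite")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()


def _validate_populations(populations: Sequence[PopulationSpec]) -> None:
    if not populations:
        raise ValueError("need >= 1 population")
    total = sum(p.abundance for p in populations)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population abundances sum to {total}, not 1")


def _lognormal10(rng: np.random.Generator, m: float, s: float, n: int) -> np.ndarray:
    return 10.0 ** rng.normal(m, s, size=n)


def simulate_well(
    populations: Sequence[PopulationSpec],
    antibody: Antibody | None,
    noise: TechnicalNoiseModel,
    seed: int | np.random.SeedSequence,
    fluor_channels: Sequence[str] = ("PE-A", "FITC-A", "APC-A"),
    viability_stained: bool = True,
    costains: Sequence[Antibody] = (),
    metadata: dict | None = None,
) -> EventTable:
    """Simulate one well's events.

    Each event belongs to one population (drawn by abundance).  Every
    fluorescence channel carries that population's autofluorescence; if an
    antibody is present, events positive for its antigen (with the
    population's positive fraction) additionally receive a log-normal
    stained signal on the antibody's detector channel.  Spillover mixes
    the fluorescence channels linearly.  Dead cells are bright in the
    viability channel (when the viability dye is present); doublets double
    FSC-A and FSC-W with FSC-H unchanged.  ``antibody=None`` with
    ``viability_stained=False`` yields a fully unstained control well
    whose channels are pure autofluorescence - the FMO reference.

    ``costains`` adds lineage co-stain antibodies (e.g. CD45/CD31/CD34/TE7
    on complementary fluorochromes) stained simultaneously with the panel
    antibody; their detector channels are appended automatically.  Stain
    positivity is drawn per population, antigens independent within a
    population.
    """
    _validate_populations(populations)
    rng = np.random.default_rng(seed)
    n = noise.events_per_well

    abundances = np.array([p.abundance for p in populations])
    pop_idx = rng.choice(len(populations), size=n, p=abundances / abundances.sum())
    dead = rng.random(n) < noise.dead_fraction
    doublet = rng.random(n) < noise.doublet_fraction

    # One jitter draw per well: shifts stained-signal log10 mean (run drift).
    jitter = rng.normal(0.0, noise.intensity_jitter_sd) if noise.intensity_jitter_sd else 0.0

    cols: dict[str, np.ndarray] = {}
    cols["FSC-A"] = _lognormal10(rng, *_FSC_A, n)
    cols["FSC-H"] = _lognormal10(rng, *_FSC_H, n)
    cols["FSC-W"] = _lognormal10(rng, *_FSC_W, n)
    cols["SSC-A"] = _lognormal10(rng, *_SSC_A, n)
    cols["FSC-A"][doublet] *= 2.0
    cols["FSC-W"][doublet] *= 2.0

    all_fluor = [VIABILITY_CHANNEL, *fluor_channels]
    for ab in costains:
        if ab.channel_name not in all_fluor:
            all_fluor.append(ab.channel_name)
    for ch in all_fluor:
        sig = np.empty(n)
        for k, pop in enumerate(populations):
            m = pop_idx == k
            am, asd = pop.af_params(ch)
            sig[m] = _lognormal10(rng, am, asd, int(m.sum()))
        cols[ch] = sig

    if viability_stained and dead.any():
        cols[VIABILITY_CHANNEL][dead] += _lognormal10(rng, *_DEAD_STAIN, int(dead.sum()))

    positive = np.zeros(n, dtype=bool)
    stains = ([antibody] if antibody is not None else []) + list(costains)
    for ab in stains:
        ch = ab.channel_name
        if ch not in cols:
            raise ValueError(f"antibody channel {ch!r} not among simulated channels")
        for k, pop in enumerate(populations):
            m = pop_idx == k
            frac = pop.positive_fraction.get(ab.antigen_name, 0.0)
            pos = m & (rng.random(n) < frac)
            if ab is antibody:
                positive |= pos
            if pos.any():
                sm, ssd = pop.stain_params(ab.antigen_name)
                cols[ch][pos] += _lognormal10(rng, sm + jitter, ssd, int(pos.sum()))

    if noise.spillover is not None:
        sp = noise.spillover
        present = [c for c in sp.channels if c in cols]
        if len(present) == len(sp.channels):
            raw = np.column_stack([cols[c] for c in sp.channels])
            mixed = raw @ sp.values
            for j, c in enumerate(sp.channels):
                cols[c] = mixed[:, j]

    meta = dict(metadata or {})
    meta.setdefault("antigen", antibody.antigen_name if antibody else None)
    meta.setdefault("channel", antibody.channel_name if antibody else None)
    meta["n_dead_planted"] = int(dead.sum())
    meta["n_doublet_planted"] = int(doublet.sum())
    meta["n_positive_planted"] = int(positive.sum())
    meta["population_labels"] = np.array([populations[k].name for k in pop_idx])
    meta["dead_mask_planted"] = dead
    meta["doublet_mask_planted"] = doublet
    df = pd.DataFrame(cols)
    return EventTable(data=df, metadata=meta)


def well_seed(master_seed: int, plate: str, well: str) -> np.random.SeedSequence:
    """Deterministic per-well seed: SeedSequence over (master, crc32(plate), crc32(well)).

    CRC32 is stable across platforms and Python versions, so plates can be
    generated in parallel yet reproducibly.
    """
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(plate.encode()), zlib.crc32(well.encode())]
    )


def simulate_screen_plate(
    pmap: PanelPlateMap,
    populations: Sequence[PopulationSpec],
    noise: TechnicalNoiseModel,
    treatment: TreatmentEffectSpec | None,
    seed: int,
    sample_id: str = "sample",
) -> dict[tuple[str, str], EventTable]:
    """Simulate every well of a plate map for one sample.

    CONTROL wells are simulated unstained (no antibody, no viability dye),
    providing the FMO reference for every channel.  A treatment, if given,
    perturbs the planted positive fractions before simulation.  Per-well
    seeds derive deterministically from the master seed.
    """
    pops = treatment.apply(populations) if treatment is not None else list(populations)
    out: dict[tuple[str, str], EventTable] = {}
    for (plate, well), entry in pmap.wells.items():
        ss = well_seed(seed, plate, well)
        meta = {
            "plate": plate,
            "well": well,
            "sample_id": sample_id,
            "master_seed": int(seed),
            "treatment": treatment.label if treatment else None,
        }
        if isinstance(entry, ControlWell):
            out[(plate, well)] = simulate_well(
                pops, None, noise, ss, viability_stained=False, metadata=meta
            )
        else:
            out[(plate, well)] = simulate_well(pops, entry, noise, ss, metadata=meta)
    return out
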