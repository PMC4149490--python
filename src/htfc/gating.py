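"""Gating: viability exclusion, singlet discrimination, FMO thresholds,
percent-positive, compensation, and lineage co-stain deconvolution.

The manual gates of an interactive cytometry analysis are replaced by
reproducible automatic equivalents:

* positivity and viability thresholds are empirical percentiles of an
  unstained (fluorescence-minus-one) control well, using the
  linear-interpolation quantile definition (``numpy.quantile`` method
  ``"linear"``: with sorted values x_1..x_n, quantile q interpolates
  linearly between the order statistics bracketing 1 + q(n-1));
* singlets are events with FSC-W at most ``singlet_width_factor`` times
  the median FSC-W of the well (doublets double their pulse width);
* gate order is fixed: viability, then singlets, then positivity; the
  percent-positive denominator is viable singlets.

An event is positive when its channel value is strictly greater than the
threshold (ties have measure zero for continuous data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import EventTable, SpilloverMatrix, VIABILITY_CHANNEL

__all__ = [
    "GateConfig",
    "GateResult",
    "CoStainGateSpec",
    "QCError",
    "fmo_threshold",
    "gate_viable",
    "gate_singlets",
    "percent_positive",
    "gate_well",
    "deconvolve_lineages",
    "apply_compensation",
]


class QCError(ValueError):
    """Raised when a well fails a quality-control precondition."""


@dataclass(frozen=True)
class GateConfig:
    viability_channel: str = VIABILITY_CHANNEL
    viability_fmo_percentile: float = 99.9
    singlet_width_factor: float = 1.5
    positivity_fmo_percentile: float = 99.9
    min_events: int = 10_000

    def __post_init__(self) -> None:
        for name in ("viability_fmo_percentile", "positivity_fmo_percentile"):
            v = getattr(self, name)
            if not 50.0 < v <= 100.0:
                raise ValueError(f"{name}={v} outside (50, 100]")
        if self.singlet_width_factor <= 1.0:
            raise ValueError("singlet_width_factor must be > 1")


@dataclass
class GateResult:
    """Masks and counts from the fixed viability -> singlet -> positivity chain.

    ``qc_pass`` is False when fewer than ``min_events`` events were
    collected in the well (the acquisition QC rule); such wells are
    reported as missing, never as zero.
    """

    masks: dict[str, np.ndarray]
    thresholds: dict[str, float]
    qc_pass: bool

    @property
    def counts(self) -> dict[str, int]:
        return {name: int(m.sum()) for name, m in self.masks.items()}

    @property
    def analysis_mask(self) -> np.ndarray:
        return self.masks["analysis"]


def fmo_threshold(control: EventTable, channel: str, percentile: float) -> float:
    """Empirical percentile of the FMO control's channel (linear interpolation)."""
    if channel not in control.channels:
        raise KeyError(f"channel {channel!r} not in control well")
    values = control[channel]
    if len(values) < 100:
        raise QCError(f"FMO control has only {len(values)} events in {channel!r} (<100)")
    return float(np.quantile(values, percentile / 100.0, method="linear"))


def gate_viable(events: EventTable, config: GateConfig, threshold: float) -> np.ndarray:
    """Viable = viability-dye signal at or below the FMO threshold."""
    ch = config.viability_channel
    if ch not in events.channels:
        raise KeyError(f"viability channel {ch!r} missing from event table")
    return events[ch] <= threshold


def gate_singlets(events: EventTable, config: GateConfig) -> np.ndarray:
    """Singlet = FSC-W at most width_factor x median FSC-W of the well."""
    for ch in ("FSC-H", "FSC-W"):
        if ch not in events.channels:
            raise KeyError(f"scatter channel {ch!r} missing from event table")
    width = events["FSC-W"]
    return width <= config.singlet_width_factor * float(np.median(width))


def percent_positive(
    events: EventTable, gates: GateResult, channel: str, threshold: float
) -> float:
    """100 x fraction of analysis (viable singlet) events strictly above threshold."""
    mask = gates.analysis_mask
    n = int(mask.sum())
    if n == 0:
        raise QCError("empty analysis mask: no viable singlet events")
    pos = events[channel][mask] > threshold
    return 100.0 * float(pos.sum()) / n


def gate_well(
    events: EventTable,
    control: EventTable,
    config: GateConfig,
    channel: str | None = None,
) -> GateResult:
    """Run the full gate chain on one well against its FMO control.

    Returns masks for viable, singlet, analysis (viable AND singlet) and,
    when ``channel`` is given, positive (within analysis).  Counts are
    non-increasing along the chain by construction.
    """
    via_thr = fmo_threshold(control, config.viability_channel, config.viability_fmo_percentile)
    viable = gate_viable(events, config, via_thr)
    singlet = gate_singlets(events, config)
    analysis = viable & singlet
    masks = {"viable": viable, "singlet": singlet, "analysis": analysis}
    thresholds = {"viability": via_thr}
    qc_pass = events.n_events >= config.min_events
    result = GateResult(masks=masks, thresholds=thresholds, qc_pass=qc_pass)
    if channel is not None:
        pos_thr = fmo_threshold(control, channel, config.positivity_fmo_percentile)
        thresholds[channel] = pos_thr
        masks["positive"] = analysis & (events[channel] > pos_thr)
    return result


@dataclass
class CoStainGateSpec:
    """Ordered lineage-assignment rules over co-stain channels.

    Each rule is ``(population name, {channel: required sign})`` with sign
    ``+1`` (above threshold) or ``-1`` (at or below threshold).  Rules are
    evaluated in order; the first match wins; events matching no rule are
    "unassigned".  The default spec reproduces the tumor deconvolution
    scheme: CD45+ immune, CD45-CD31+CD34+ endothelial, CD45-TE7+
    fibroblast, quad-negative cancer.
    """

    rules: list[tuple[str, dict[str, int]]]

    @classmethod
    def tumor_default(
        cls,
        cd45: str = "APC-Cy7-A",
        cd31: str = "PE-Cy7-A",
        cd34: str = "PerCP-Cy5.5-A",
        te7: str = "eFluor450-A",
    ) -> "CoStainGateSpec":
        return cls(
            rules=[
                ("immune", {cd45: +1}),
                ("endothelial", {cd45: -1, cd31: +1, cd34: +1}),
                ("fibroblast", {cd45: -1, te7: +1}),
                ("cancer", {cd45: -1, cd31: -1, cd34: -1, te7: -1}),
            ]
        )


def deconvolve_lineages(
    events: EventTable,
    spec: CoStainGateSpec,
    thresholds: Mapping[str, float],
    analysis_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Assign each analysis event to the first matching lineage rule.

    Returns disjoint masks per population plus "unassigned"; their union
    equals the analysis mask.
    """
    if analysis_mask is None:
        analysis_mask = np.ones(events.n_events, dtype=bool)
    unclaimed = analysis_mask.copy()
    out: dict[str, np.ndarray] = {}
    for name, conditions in spec.rules:
        match = unclaimed.copy()
        for ch, sign in conditions.items():
            if ch not in events.channels:
                raise KeyError(f"co-stain rule {name!r} references absent channel {ch!r}")
            if ch not in thresholds:
                raise KeyError(f"no FMO threshold provided for channel {ch!r}")
            above = events[ch] > thresholds[ch]
            match &= above if sign > 0 else ~above
        out[name] = match
        unclaimed &= ~match
    out["unassigned"] = unclaimed
    return out


def apply_compensation(events: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Unmix fluorescence channels: observed row-vectors times inverse(spillover).

    Channels not listed in the spillover matrix (scatter, viability unless
    listed) pass through untouched.
    """
    missing = [c for c in spill.channels if c not in events.channels]
    if missing:
        raise KeyError(f"spillover channels absent from events: {missing}")
    observed = events.data[list(spill.channels)].to_numpy()
    corrected = observed @ spill.inverse()
    data = events.data.copy()
    data[list(spill.channels)] = corrected
    return EventTable(data=data, metadata=dict(events.metadata))
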