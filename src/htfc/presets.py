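"""Default simulation conditions for the demo screen.

The demo sample emulates a mixed-lineage cell pool (epithelial cancer
cells, hematopoietic cells, fibroblasts pooled to maximise epitope
coverage) profiled against the packaged 24-antibody panel.  Per-antigen
positive fractions span the full dynamic range - lineage-restricted
markers near 0 or 1 within a population, broadly expressed markers high
everywhere - so that the pooled percent-positive profile has the rank
structure reproducibility statistics need.

These values define the study conditions for every test and for the
acceptance analysis; they are data-like constants, not tuning knobs.
"""

from __future__ import annotations

from .panel import demo_plate_map
from .simulate import (
    PopulationSpec,
    SpilloverMatrix,
    TechnicalNoiseModel,
    TreatmentEffectSpec,
    default_spillover,
)

__all__ = [
    "default_populations",
    "default_noise",
    "digestion_treatment",
    "DEMO_LABILE_ANTIGENS",
    "lineage_populations",
]

# Pooled-sample composition: epithelial-dominant with substantial immune
# and fibroblast fractions, as in a pooled cell-line + PBMC mixture.
_EPITHELIAL = {
    "CD326": 0.95, "CD24": 0.80, "CD29": 0.90, "CD9": 0.85, "CD49f": 0.60,
    "CD44": 0.70, "CD47": 0.92, "CD59": 0.96, "CD166": 0.72, "CD54": 0.35,
    "CD10": 0.12, "CD73": 0.30, "CD105": 0.08, "CD146": 0.05, "CD141": 0.04,
    "CD90": 0.06, "CD45": 0.01, "CD3": 0.00, "CD4": 0.01, "CD8": 0.00,
    "CD11b": 0.01, "CD31": 0.01, "CD34": 0.02, "CD144": 0.01,
}
_IMMUNE = {
    "CD45": 0.99, "CD3": 0.62, "CD4": 0.40, "CD8": 0.24, "CD11b": 0.30,
    "CD44": 0.92, "CD47": 0.95, "CD59": 0.90, "CD9": 0.28, "CD29": 0.55,
    "CD54": 0.45, "CD24": 0.20, "CD166": 0.10, "CD49f": 0.05, "CD10": 0.08,
    "CD73": 0.10, "CD105": 0.02, "CD146": 0.02, "CD141": 0.03, "CD90": 0.02,
    "CD31": 0.08, "CD34": 0.01, "CD144": 0.00, "CD326": 0.00,
}
_FIBROBLAST = {
    "CD90": 0.90, "CD73": 0.88, "CD105": 0.80, "CD29": 0.95, "CD44": 0.85,
    "CD10": 0.55, "CD146": 0.25, "CD54": 0.40, "CD49f": 0.30, "CD9": 0.60,
    "CD47": 0.90, "CD59": 0.93, "CD166": 0.55, "CD24": 0.05, "CD141": 0.10,
    "CD45": 0.00, "CD3": 0.00, "CD4": 0.00, "CD8": 0.00, "CD11b": 0.00,
    "CD31": 0.02, "CD34": 0.05, "CD144": 0.01, "CD326": 0.01,
}

#: Antigens the demo digestion treatment perturbs strongly (planted truth).
DEMO_LABILE_ANTIGENS = ("CD24", "CD326", "CD49f", "CD166", "CD54")


def default_populations() -> list[PopulationSpec]:
    """The pooled mixed-lineage demo sample (epithelial / immune / fibroblast)."""
    return [
        PopulationSpec("epithelial", 0.45, _EPITHELIAL),
        PopulationSpec("immune", 0.35, _IMMUNE),
        PopulationSpec("fibroblast", 0.20, _FIBROBLAST),
    ]


def default_noise(**overrides) -> TechnicalNoiseModel:
    """Default acquisition model: 10,000 events/well, 5% dead, 3% doublets,
    mild 3-colour spillover, 0.05 log10 units of per-well intensity jitter."""
    kwargs = dict(
        events_per_well=10_000,
        dead_fraction=0.05,
        doublet_fraction=0.03,
        spillover=default_spillover(),
        intensity_jitter_sd=0.05,
    )
    kwargs.update(overrides)
    return TechnicalNoiseModel(**kwargs)


def digestion_treatment(factor: float = 0.2) -> TreatmentEffectSpec:
    """Enzymatic-digestion surrogate: scales the planted positive fraction of
    each labile demo antigen by ``factor`` (default 0.2, i.e. a 5-fold loss)."""
    return TreatmentEffectSpec(
        label="digestion",
        effects={ag: ("scale", factor) for ag in DEMO_LABILE_ANTIGENS},
    )


def lineage_populations() -> list[PopulationSpec]:
    """A 4-population tumor-like mixture for lineage deconvolution demos:
    cancer cells, CD45+ immune cells, CD45-CD31+CD34+ endothelium, and
    CD45-TE7+ fibroblasts at 0.4/0.4/0.1/0.1 abundance."""
    return [
        PopulationSpec(
            "cancer", 0.40,
            {"CD45": 0.0, "CD31": 0.0, "CD34": 0.0, "TE7": 0.0, "CD326": 0.9},
        ),
        PopulationSpec(
            "immune", 0.40,
            {"CD45": 1.0, "CD31": 0.0, "CD34": 0.0, "TE7": 0.0},
        ),
        PopulationSpec(
            "endothelial", 0.10,
            {"CD45": 0.0, "CD31": 1.0, "CD34": 1.0, "TE7": 0.0},
        ),
        PopulationSpec(
            "fibroblast", 0.10,
            {"CD45": 0.0, "CD31": 0.0, "CD34": 0.0, "TE7": 1.0},
        ),
    ]
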