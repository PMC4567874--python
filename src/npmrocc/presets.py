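"""Default study conditions for the synthetic generator.

Three survey profiles mirror the structure of the Great Basin spotted
frog datasets the analyses were designed around: a small Idaho-style
dataset (n = 78, naive occupancy 0.28), a large Nevada-style dataset
(n = 778, occupancy 0.14) and a small Oregon-style dataset (n = 75,
occupancy 0.15).  Each comes with a multiplicative true surface whose
active predictors echo the final habitat models for those datasets
(maximum depth, emergent vegetation, vegetation height, habitat type,
fish status) plus pure-noise covariates for selection experiments.

Covariate distributions are invented (the underlying field data are not
public) but chosen to be field-realistic: depths of a few metres at
most, emergent vegetation as a shoreline percentage, vegetation heights
in cm, habitat-class frequencies dominated by streams and stock
ponds/reservoirs with beaver ponds uncommon.
"""

from __future__ import annotations

from .simulate import ContinuousEffect, DatasetProfile, TrueSurface

__all__ = [
    "idaho_profile", "idaho_surface",
    "nevada_profile", "nevada_surface",
    "oregon_profile", "oregon_surface",
]

_HABITAT_FREQS = {
    "beaver pond": 0.18,
    "stream": 0.30,
    "pond": 0.14,
    "reservoir/stock pond": 0.28,
    "spring/seep": 0.10,
}

# beaver ponds are by far the most suitable habitat class; springs/seeps
# and stock ponds the least
_HABITAT_MULT = {
    "beaver pond": 1.0,
    "stream": 0.35,
    "pond": 0.25,
    "reservoir/stock pond": 0.18,
    "spring/seep": 0.08,
}

_FISH_FREQS = {"no fish": 0.50, "nontrout": 0.20, "trout": 0.30}
# trout are predators of larvae; nontrout fish co-occur with good frog habitat
_FISH_MULT = {"no fish": 0.60, "nontrout": 1.0, "trout": 0.45}


def idaho_profile(n_sites: int = 78, target_occupancy: float = 0.28
                  ) -> DatasetProfile:
    """Small-dataset profile: habitat type + depth drive occupancy."""
    return DatasetProfile(
        name="ID",
        n_sites=n_sites,
        target_occupancy=target_occupancy,
        covariate_distributions={
            "max_depth": {"kind": "uniform", "low": 0.1, "high": 2.6},
            "habitat": {"kind": "categorical", "freqs": dict(_HABITAT_FREQS)},
            "emergent_veg": {"kind": "uniform", "low": 0.0, "high": 100.0},
            "grazing": {"kind": "categorical",
                        "freqs": {"none/light": 0.45, "moderate": 0.35,
                                  "heavy": 0.20}},
        },
    )


def idaho_surface() -> TrueSurface:
    """Occupancy rises with depth and peaks in beaver ponds; emergent
    vegetation and grazing carry no effect (noise predictors)."""
    return TrueSurface(
        base_rate=0.9,
        continuous_effects=(
            ContinuousEffect("max_depth", "gaussian", center=1.8, width=1.5),
        ),
        categorical_effects={"habitat": dict(_HABITAT_MULT)},
        noise_predictors=("emergent_veg", "grazing"),
    )


def nevada_profile(n_sites: int = 778, target_occupancy: float = 0.14
                   ) -> DatasetProfile:
    """Large-dataset profile: depth, emergent vegetation and fish status
    drive occupancy; four covariates are pure noise."""
    return DatasetProfile(
        name="NV",
        n_sites=n_sites,
        target_occupancy=target_occupancy,
        covariate_distributions={
            "max_depth": {"kind": "uniform", "low": 0.1, "high": 2.6},
            "emergent_veg": {"kind": "uniform", "low": 0.0, "high": 100.0},
            "fish_status": {"kind": "categorical", "freqs": dict(_FISH_FREQS)},
            "elevation": {"kind": "uniform", "low": 1400.0, "high": 2600.0},
            "shore_slope": {"kind": "uniform", "low": 0.0, "high": 45.0},
            "grazing": {"kind": "categorical",
                        "freqs": {"low": 0.40, "moderate": 0.35, "heavy": 0.25}},
            "connectivity": {"kind": "categorical",
                             "freqs": {"permanent": 0.50, "seasonal": 0.30,
                                       "isolated": 0.20}},
        },
    )


def nevada_surface() -> TrueSurface:
    """Deep, well-vegetated water bodies without trout are most likely
    occupied; elevation, shore slope, grazing and connectivity are noise."""
    return TrueSurface(
        base_rate=0.6,
        continuous_effects=(
            ContinuousEffect("max_depth", "gaussian", center=2.0, width=0.6),
            ContinuousEffect("emergent_veg", "sigmoid", center=30.0, width=10.0),
        ),
        categorical_effects={"fish_status": dict(_FISH_MULT)},
        noise_predictors=("elevation", "shore_slope", "grazing", "connectivity"),
    )


def oregon_profile(n_sites: int = 75, target_occupancy: float = 0.15
                   ) -> DatasetProfile:
    """Small-dataset profile: habitat type, vegetation height and depth."""
    return DatasetProfile(
        name="OR",
        n_sites=n_sites,
        target_occupancy=target_occupancy,
        covariate_distributions={
            "habitat": {"kind": "categorical", "freqs": dict(_HABITAT_FREQS)},
            "veg_height": {"kind": "uniform", "low": 0.0, "high": 165.0},
            "max_depth": {"kind": "uniform", "low": 0.1, "high": 2.1},
            "grazed": {"kind": "categorical",
                       "freqs": {"ungrazed": 0.45, "grazed": 0.55}},
        },
    )


def oregon_surface() -> TrueSurface:
    """Occupancy peaks at intermediate vegetation heights and in beaver
    ponds, rising with depth; grazed/ungrazed is a noise predictor."""
    return TrueSurface(
        base_rate=0.8,
        continuous_effects=(
            ContinuousEffect("veg_height", "gaussian", center=47.0, width=40.0),
            ContinuousEffect("max_depth", "gaussian", center=1.8, width=1.5),
        ),
        categorical_effects={"habitat": dict(_HABITAT_MULT)},
        noise_predictors=("grazed",),
    )
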