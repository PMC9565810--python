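import numpy as np
import pytest

from fenestra.geometry import RegionModel
from fenestra.synth import GeneratorConfig, PathwayRates, generate_tracks


@pytest.fixture(scope="session")
def geometry() -> RegionModel:
    return RegionModel()


@pytest.fixture(scope="session")
def balanced_ensemble():
    """A mid-size synthetic ensemble with all six crossing streams active."""
    cfg = GeneratorConfig(
        rates=PathwayRates(
            tm_inward=0.08,
            tm_outward=0.08,
            lat_inward=0.25,
            lat_outward=0.25,
            api_inward=0.02,
            api_outward=0.02,
        ),
        duration=80.0,
        seed=2024,
        n_ions=30,
        n_vest_init=4,
    )
    tracks, truth = generate_tracks(cfg)
    return cfg, tracks, truth


def make_track(z_values, ion_id="ion", species="chloride", box_z=170.0, xy=(0.0, 0.0)):
    """Axis-aligned track through the given z waypoints, one per frame."""
    from fenestra.tracks import IonTrack

    z = np.asarray(z_values, dtype=float)
    pos = np.column_stack([np.full_like(z, xy[0]), np.full_like(z, xy[1]), z])
    return IonTrack(
        ion_id=ion_id,
        species=species,
        times=np.arange(len(z), dtype=float),
        positions=pos,
        box_z=np.full(len(z), box_z),
    )
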