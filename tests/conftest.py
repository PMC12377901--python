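import pytest

from dsbquant import DropletCounts, LaneVolumes, calibrate_droplet_volume

# Published chip: 23,527 analyzable droplets; positives per gated population.
N_DROPLETS = 23_527
K_BLUE_TOTAL = 4_516
K_BLUE_JEM1 = 2_863
K_GREEN_JEM1 = 2_844
C_GREEN_JEM1 = 206.6  # vendor-reported cp/µL for the green population


@pytest.fixture(scope="session")
def chip_counts() -> dict[str, DropletCounts]:
    return {
        "blue_total": DropletCounts(N_DROPLETS, K_BLUE_TOTAL, "blue double population"),
        "blue_jem1": DropletCounts(N_DROPLETS, K_BLUE_JEM1, "blue upper (JEM1)"),
        "green_jem1": DropletCounts(N_DROPLETS, K_GREEN_JEM1, "green JEM1"),
    }


@pytest.fixture(scope="session")
def calibrated_volume(chip_counts) -> float:
    """Effective droplet volume back-derived from the green-channel row."""
    return calibrate_droplet_volume(chip_counts["green_jem1"], C_GREEN_JEM1)


@pytest.fixture(scope="session")
def lane_sample1() -> LaneVolumes:
    return LaneVolumes(
        u1=1_595_996, u2=304_624, u3=1_372_968, u4=528_404,
        u5=2_446_924, u6=1_375_188, u7=742_804, u8=520_004,
        sample_id="sample1",
    )


@pytest.fixture(scope="session")
def lane_sample2() -> LaneVolumes:
    return LaneVolumes(
        u1=1_719_524, u2=1_030_168, u3=14_037_895, u4=1_606_612,
        u5=3_526_660, u6=2_321_516, u7=1_634_544, u8=544_948,
        sample_id="sample2",
    )
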