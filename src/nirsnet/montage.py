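"""48-channel frontotemporal optode montage.

The probe array emulated here covers the theory-of-mind network with 15
sources and 16 detectors at a fixed 3 cm source-detector separation, giving
48 measurement channels grouped into six anatomical regions: inferior,
middle, superior and superior-medial frontal gyri (IFG, MFG, SFG, SMFG),
the temporo-parietal junction (TPJ) and the superior temporal gyrus (STG),
on each hemisphere.

The packaged coordinate table is a synthetic stand-in: region and
hemisphere labels follow the anatomical groupings of the emulated layout,
while the MNI coordinates are plausible constructed values, not digitized
probe positions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

REGIONS = ("IFG", "MFG", "SFG", "SMFG", "TPJ", "STG")
HEMISPHERES = ("left", "right", "midline")
N_CHANNELS = 48
SOURCE_DETECTOR_DISTANCE_CM = 3.0

_FIXTURE = "montage48_synthetic.tsv"


def make_montage() -> pd.DataFrame:
    """Return the packaged 48-channel montage table.

    Columns: ``channel_id, source_id, detector_id, x, y, z, region,
    hemisphere``. Deterministic: repeated calls return equal tables.
    """
    ref = resources.files("nirsnet.data").joinpath(_FIXTURE)
    with ref.open("r") as fh:
        table = pd.read_csv(fh, sep="\t")
    validate_montage(table)
    return table


def validate_montage(table: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *table* is not a valid 48-channel montage."""
    required = {"channel_id", "source_id", "detector_id", "region", "hemisphere"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"montage missing columns: {sorted(missing)}")
    if len(table) != N_CHANNELS:
        raise ValueError(f"montage must have {N_CHANNELS} channels, got {len(table)}")
    ids = table["channel_id"].to_numpy()
    if sorted(ids.tolist()) != list(range(1, N_CHANNELS + 1)):
        raise ValueError("channel_ids must be unique and contiguous 1..48")
    bad_region = set(table["region"]) - set(REGIONS)
    if bad_region:
        raise ValueError(f"unknown region labels: {sorted(bad_region)}")
    bad_hemi = set(table["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")


def region_blocks(table: pd.DataFrame) -> dict[tuple[str, str], list[int]]:
    """Group 0-based channel indices by (region, hemisphere)."""
    blocks: dict[tuple[str, str], list[int]] = {}
    for idx, row in enumerate(table.itertuples(index=False)):
        blocks.setdefault((row.region, row.hemisphere), []).append(idx)
    return blocks
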