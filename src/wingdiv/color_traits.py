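"""Species-level wing-color traits from specimen images.

Color is summarized per wing region as the *mode* of each 8-bit channel
(red, green, blue) and of the per-pixel channel sum ("total", 0..765) over
the masked pixels.  With four regions (whole wing plus three vein-delimited
cells) and four channels this yields 16 traits per species; specimens are
aggregated to species by the arithmetic mean of their modes.  A
lightness-independent index is available as the residual of each channel
trait regressed on that region's lightness across species, which removes
variation in overall brightness and leaves hue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REGIONS = ("wing", "cell1", "cell2", "cell3")
CHANNELS = ("red", "green", "blue", "total")
TRAIT_COLUMNS = tuple(f"{r}_{c}" for r in REGIONS for c in CHANNELS)

__all__ = [
    "REGIONS",
    "CHANNELS",
    "TRAIT_COLUMNS",
    "SpecimenMeasurement",
    "mode_channel",
    "measure_region",
    "aggregate_species",
    "lightness_index",
    "read_trait_table",
    "write_trait_table",
]


@dataclass(frozen=True)
class SpecimenMeasurement:
    species: str
    region: str
    mode_red: int
    mode_green: int
    mode_blue: int
    mode_total: int

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        for v in (self.mode_red, self.mode_green, self.mode_blue):
            if not (0 <= v <= 255):
                raise ValueError("channel mode out of 0..255")
        if not (0 <= self.mode_total <= 765):
            raise ValueError("total mode out of 0..765")

    def value(self, channel: str) -> int:
        return getattr(self, f"mode_{channel}")


def mode_channel(pixels, mask=None, channel: str = "red") -> int:
    """Most frequent value of a channel over the masked pixels.

    ``channel`` is one of red/green/blue/total; "total" is the per-pixel
    R+G+B sum, with the mode taken over that sum.  Ties break to the
    smallest value.  Accepts a :class:`WingRegionFixture`-like object
    (with ``.pixels`` and ``.mask``) or a raw H x W x 3 array plus mask.
    """
    if hasattr(pixels, "pixels"):
        if mask is None:
            mask = pixels.mask
        pixels = pixels.pixels
    pixels = np.asarray(pixels)
    if mask is None:
        mask = np.ones(pixels.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no pixels selected")
    sel = pixels[mask].astype(np.int64)
    if channel == "total":
        vals = sel.sum(axis=1)
    else:
        try:
            ci = ("red", "green", "blue").index(channel)
        except ValueError:
            raise ValueError(f"unknown channel {channel!r}") from None
        vals = sel[:, ci]
    counts = np.bincount(vals)
    return int(counts.argmax())  # argmax returns the first (smallest) tie


def measure_region(species: str, region: str, pixels, mask=None) -> SpecimenMeasurement:
    """All four channel modes of one wing region of one specimen."""
    return SpecimenMeasurement(
        species=species,
        region=region,
        mode_red=mode_channel(pixels, mask, "red"),
        mode_green=mode_channel(pixels, mask, "green"),
        mode_blue=mode_channel(pixels, mask, "blue"),
        mode_total=mode_channel(pixels, mask, "total"),
    )


def aggregate_species(measurements, tip_names) -> pd.DataFrame:
    """Species x 16-trait table: mean of specimen modes, 2 decimals.

    Every tree tip must be covered by at least one measurement for every
    region.  The result is row-indexed by species in ``tip_names`` order
    with :data:`TRAIT_COLUMNS` columns — the exact input of the trait
    evolution and tip-rate modules.
    """
    acc: dict = {}
    for m in measurements:
        for c in CHANNELS:
            acc.setdefault((m.species, f"{m.region}_{c}"), []).append(m.value(c))
    rows = {}
    for sp in tip_names:
        row = {}
        for col in TRAIT_COLUMNS:
            vals = acc.get((sp, col))
            if not vals:
                raise ValueError(f"species {sp!r} has no measurement for {col}")
            row[col] = round(float(np.mean(vals)), 2)
        rows[sp] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[list(TRAIT_COLUMNS)]
    df.index.name = "species"
    return df


def lightness_index(table: pd.DataFrame) -> pd.DataFrame:
    """Residuals of each channel trait regressed on its region's lightness.

    Lightness of a region is its total mode divided by 3.  For each of the
    12 channel traits (R, G, B per region) an ordinary least-squares
    regression against lightness across species is fitted and the residuals
    returned; residuals of each trait sum to zero.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 species for the regression")
    out = {}
    for region in REGIONS:
        light = table[f"{region}_total"].to_numpy(dtype=float) / 3.0
        if np.ptp(light) == 0:
            raise ValueError(f"region {region!r} has constant lightness")
        X = np.column_stack([np.ones_like(light), light])
        for channel in ("red", "green", "blue"):
            col = f"{region}_{channel}"
            y = table[col].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            out[col] = y - X @ beta
    df = pd.DataFrame(out, index=table.index)
    df.index.name = "species"
    return df


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "species"
    return df
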