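"""Bundled example data.

The package ships ten years (2010-2019) of monthly mean wind speeds, in
m/s, from weather stations in three districts of Surat Thani province,
southern Thailand — Khiri Rat Nikhom, Koh Samui and Kanchanadit — 50
observations per district.  Each district's speeds are well described by a
two-parameter Weibull distribution, which makes the dataset the package's
worked example for common-mean interval estimation.
"""

from __future__ import annotations

from importlib import resources

from .core import ObservedSample
from .io import read_samples

__all__ = ["load_surat_thani", "FIXTURES"]

FIXTURES = {"surat_thani": "surat_thani_wind.csv"}


def load_surat_thani() -> list[ObservedSample]:
    """The three Surat Thani wind-speed groups, 50 monthly values each."""
    return load_fixture("surat_thani")


def load_fixture(name: str) -> list[ObservedSample]:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    ref = resources.files("weibullmeans.data").joinpath(FIXTURES[name])
    with resources.as_file(ref) as path:
        return read_samples(path)
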