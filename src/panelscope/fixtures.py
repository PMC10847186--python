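"""Bundled reference data.

``load_healthy_blood_table`` returns the published healthy-peripheral-blood
OER table for 32 neutrophil panels (transcribed percentages; N = 32), the
canonical regression surface for the classification rules.  Two of the 32
rows are internally inconsistent in the published source (their interval
percentages plus OER_>60 sum to 96.87%, leaving one population unaccounted);
their reconstructed bin counts therefore sum to 31 and the corresponding
profiles are built in non-strict mode.

``synthetic_panel_stub_path`` points at a GMT file carrying the 32 panel
*names* with SYNTHETIC placeholder gene lists — the published member-gene
lists live in supplementary material that is not redistributed here.  Use it
for name-level plumbing only, never for scoring real data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .oer import OERProfile, frame_to_profiles

HEALTHY_BLOOD_N = 32

__all__ = [
    "HEALTHY_BLOOD_N",
    "load_healthy_blood_table",
    "load_healthy_blood_profiles",
    "synthetic_panel_stub_path",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("panelscope").joinpath("data", name))


def load_healthy_blood_table() -> pd.DataFrame:
    """Printed OER percentages and published class for the 32 panels."""
    return pd.read_csv(_data_path("healthy_blood_oer.tsv"), sep="\t")


def load_healthy_blood_profiles() -> list[tuple[OERProfile, str]]:
    """(profile, published class) pairs reconstructed from the printed table."""
    frame = load_healthy_blood_table()
    return [(p, lab) for p, lab in frame_to_profiles(frame, default_n=HEALTHY_BLOOD_N)]


def synthetic_panel_stub_path() -> Path:
    return _data_path("healthy_blood_panels_synthetic.gmt")
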