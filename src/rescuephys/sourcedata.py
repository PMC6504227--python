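"""Optional real source-data loading for the published figure statistics.

The per-animal spreadsheets that accompany the article are not
redistributable inside this repository; when a user downloads them and
converts each sheet to the long cohort-table CSV schema
(``animal_id, genotype, cre, tmx, endpoint, value``) under
``data/source_data/``, the loaders here feed the real-data acceptance
checks. Expected file names:

- ``fig1_data1.csv``   — staged flurothyl latencies, TMX-naive cohort
  (endpoints ``1st clonus``, ``T/C``, ``THE``)
- ``fig2_data1.csv``   — wake spike rates pre/post TMX (endpoint
  ``wake_rate``, tmx ``-``/``+``)
- ``fig2_data2.csv``   — wake and sleep spike rates, mutants pre-TMX
  (endpoints ``wake_rate``, ``sleep_rate``)
- ``fig4_data1.csv``   — remote suppression ratios, constitutive cohort
  (endpoint ``suppression_ratio``)
- ``fig4_data2.csv``   — remote suppression ratios, lox-stop cohort
- ``fig4_data4.csv``   — four-group TMX-naive suppression ratios

All loaders return ``None`` when the file is absent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from rescuephys.io import read_cohort

DEFAULT_DIR = Path("data") / "source_data"

FILES = {
    "fig1_data1": "fig1_data1.csv",
    "fig2_data1": "fig2_data1.csv",
    "fig2_data2": "fig2_data2.csv",
    "fig4_data1": "fig4_data1.csv",
    "fig4_data2": "fig4_data2.csv",
    "fig4_data4": "fig4_data4.csv",
}


def load(name: str, data_dir: Path | str = DEFAULT_DIR) -> Optional[pd.DataFrame]:
    """Load one converted source-data table, or None if not provided."""
    if name not in FILES:
        raise KeyError(f"unknown source-data table {name!r}")
    path = Path(data_dir) / FILES[name]
    if not path.exists():
        return None
    return read_cohort(path)


def available(data_dir: Path | str = DEFAULT_DIR) -> list[str]:
    return [name for name in FILES if (Path(data_dir) / FILES[name]).exists()]
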