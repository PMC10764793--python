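"""Bundled reference data.

The published per-specimen evaluation of the two-band (446.6 nm / 632 nm)
phase classifier on ten pathologist-stained ex-vivo breast specimens,
scored at 632 nm over three acquisition runs per specimen.  These printed
rows serve as inputs to the reporting utilities (mean-row reproduction,
complement-identity checks); nothing in this module is computed.
"""

from __future__ import annotations

import pandas as pd

from .classify_eval import ConfusionCounts

__all__ = ["ten_specimen_table", "sample5_confusion"]

# Specimen id -> (Sen %, Spec %, FN ratio %, FP ratio %)
_TEN_SPECIMEN_ROWS = {
    "1": (98.93, 97.3, 1.07, 2.7),
    "2": (91.5, 93.5, 8.5, 6.5),
    "3": (88.3, 93.5, 11.7, 6.5),
    "4": (91.5, 93.0, 8.5, 7.0),
    "5": (91.6, 95.2, 8.4, 4.8),
    "6": (88.7, 92.8, 11.3, 7.2),
    "7": (87.0, 94.1, 13.0, 5.9),
    "8": (90.5, 94.1, 9.5, 5.9),
    "9": (90.8, 93.6, 9.2, 6.4),
    "10": (90.2, 93.0, 9.8, 7.0),
}


def ten_specimen_table() -> pd.DataFrame:
    """The ten-specimen stained-study evaluation, one row per specimen."""
    records = [
        {
            "sample_id": sid,
            "sen_pct": sen,
            "spec_pct": spec,
            "fn_ratio_pct": fn,
            "fp_ratio_pct": fp,
        }
        for sid, (sen, spec, fn, fp) in _TEN_SPECIMEN_ROWS.items()
    ]
    return pd.DataFrame.from_records(records)


def sample5_confusion(per_class: int = 1000) -> ConfusionCounts:
    """Confusion counts consistent with specimen #5's reported ratios.

    With ``per_class`` pixels in each class, Sen 91.6 % and Spec 95.2 %
    correspond to TP=916/FN=84 and TN=952/FP=48 (at the default size).
    """
    sen, spec = 0.916, 0.952
    tp = round(sen * per_class)
    tn = round(spec * per_class)
    return ConfusionCounts(TP=tp, FN=per_class - tp, TN=tn, FP=per_class - tn)
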