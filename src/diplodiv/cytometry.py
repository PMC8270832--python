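"""Flow-cytometry genome-size arithmetic.

C-values from fluorescence ratios against a reference standard (default:
chicken erythrocytes, haploid genome 1140 Mbp) and the pg <-> Mbp
conversion (1 pg = 978 Mbp). Instrument acquisition, gating and peak
picking are out of scope; inputs are mean fluorescences.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: 1 pg of DNA corresponds to 978 Mbp
MBP_PER_PG = 978.0

#: chicken erythrocyte standard, haploid genome size in Mbp (1.14 Gbp)
CHICKEN_REF_MBP = 1140.0


@dataclass
class CValueResult:
    sample_id: str
    mean_fluor: float
    ref_fluor: float
    c_value_mbp: float

    @property
    def c_value_pg(self) -> float:
        return self.c_value_mbp / MBP_PER_PG


def c_value(
    sample_fluor: float, ref_fluor: float, ref_c_mbp: float = CHICKEN_REF_MBP
) -> float:
    """Haploid genome size in Mbp: ref_c_mbp * sample_fluor / ref_fluor."""
    if sample_fluor <= 0 or ref_fluor <= 0 or ref_c_mbp <= 0:
        raise ValueError("fluorescences and reference size must be positive")
    return ref_c_mbp * sample_fluor / ref_fluor


def pg_to_mbp(pg: float) -> float:
    if pg < 0:
        raise ValueError("DNA mass must be non-negative")
    return pg * MBP_PER_PG


def mbp_to_pg(mbp: float) -> float:
    if mbp < 0:
        raise ValueError("genome size must be non-negative")
    return mbp / MBP_PER_PG


def replicate_c_values(
    replicates: pd.DataFrame, ref_fluor: float, ref_c_mbp: float = CHICKEN_REF_MBP
) -> pd.DataFrame:
    """Per-sample mean C-value over technical replicates, with CV.

    ``replicates`` has columns (sample_id, fluorescence); one row per
    technical replicate. The coefficient of variation is reported so runs
    can be checked against the ~2% expected for technical replicates.
    """
    if not {"sample_id", "fluorescence"} <= set(replicates.columns):
        raise ValueError("replicates needs columns sample_id, fluorescence")
    rows = []
    for sid, grp in replicates.groupby("sample_id", sort=False):
        vals = grp["fluorescence"].astype(float)
        if (vals <= 0).any():
            raise ValueError(f"{sid}: non-positive fluorescence")
        mean_f = float(vals.mean())
        mbp = c_value(mean_f, ref_fluor, ref_c_mbp)
        rows.append(
            {
                "sample_id": sid,
                "n_replicates": len(vals),
                "mean_fluor": mean_f,
                "cv": float(vals.std(ddof=1) / mean_f) if len(vals) > 1 else 0.0,
                "c_value_mbp": mbp,
                "c_value_pg": mbp_to_pg(mbp),
            }
        )
    return pd.DataFrame(rows)
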