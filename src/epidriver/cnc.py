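"""Closest-normal-cell (CNC) inference.

For each cancer cohort, the CNC is the normal cell type whose pooled
pseudobulk profile best correlates with the cohort's tumour samples:
Pearson r is computed per (tumour sample, candidate normal type) over an
explicit marker feature set, summarized per type by the median across
tumour samples, and the argmax wins.  The feature set (typically a union
of tissue- and cancer-specific differential features) is always passed
in; this module never chooses features itself.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def pseudobulk_profiles(matrix: np.ndarray, feature_ids, cell_groups) -> pd.DataFrame:
    """Mean feature profile per cell group (feature x group frame)."""
    groups = pd.Series(list(cell_groups))
    cols = {}
    for g, idx in groups.groupby(groups).groups.items():
        cols[g] = matrix[:, np.asarray(idx)].mean(axis=1)
    return pd.DataFrame(cols, index=list(feature_ids))


def infer_cnc(
    tumor_sample_profiles: pd.DataFrame,
    normal_type_profiles: pd.DataFrame,
    feature_set,
):
    """Select the closest normal cell type for a cohort.

    Parameters
    ----------
    tumor_sample_profiles, normal_type_profiles
        Feature x sample and feature x type pseudobulk frames.
    feature_set
        Features over which correlation is computed; must be non-empty and
        present in both frames.

    Returns
    -------
    (medians, cnc) : per-type median Pearson r across tumour samples, and
    the selected type.  Median ties select the lexicographically smallest
    type with a warning.
    """
    features = list(feature_set)
    if not features:
        raise ValueError("feature_set must be non-empty")
    if len(normal_type_profiles.columns) < 2:
        raise ValueError("need at least two candidate normal types")
    if len(tumor_sample_profiles.columns) < 1:
        raise ValueError("need at least one tumour sample")
    T = tumor_sample_profiles.loc[features]
    N = normal_type_profiles.loc[features]
    for frame, kind in ((T, "tumour sample"), (N, "normal type")):
        sd = frame.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = sd.index[sd == 0][0]
            raise ValueError(f"zero-variance profile for {kind} {bad!r}")
    r = pd.DataFrame(index=T.columns, columns=N.columns, dtype=float)
    for t in T.columns:
        for n in N.columns:
            r.loc[t, n] = float(np.corrcoef(T[t], N[n])[0, 1])
    medians = r.median(axis=0)
    best = medians.max()
    winners = sorted(medians.index[medians == best])
    if len(winners) > 1:
        warnings.warn(f"median correlation tie between {winners}; selecting {winners[0]}")
    return medians, winners[0]
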