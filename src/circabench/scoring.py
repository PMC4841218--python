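"""In-group recoding of raw IAT D scores.

Positive raw D indicates a preference for the majority (White) targets.  To
put every participant on a common in-group-preference scale, the score is
sign-flipped for members of the designated reverse-coded group(s) (by
default Black participants, with the older "Black-not Hispanic" label as an
alias), so that positive values always mean preference for one's own group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_REVERSE_GROUPS = frozenset({"Black", "Black-not Hispanic"})


def recode_ingroup(d_raw, race, reverse_groups=DEFAULT_REVERSE_GROUPS):
    """Return the in-group-coded score: -d_raw for reverse groups, else d_raw.

    Scalar or vectorized.  ``race`` must be non-missing; for scalar input a
    missing race raises ValueError (analyses require race).
    """
    if np.isscalar(race) or race is None or isinstance(race, str):
        if race is None or (isinstance(race, float) and np.isnan(race)):
            raise ValueError("race is missing; record must be excluded")
        return -d_raw if race in reverse_groups else d_raw
    race = pd.Series(race)
    flip = race.isin(list(reverse_groups)).to_numpy()
    return np.where(flip, -np.asarray(d_raw, dtype=float), d_raw)


def recode_frame(
    df: pd.DataFrame,
    d_col: str = "d_raw",
    race_col: str = "race",
    reverse_groups=DEFAULT_REVERSE_GROUPS,
    out_col: str = "d_ingroup",
) -> pd.DataFrame:
    """Add the in-group-coded outcome column; drop rows with missing race.

    The number of rows dropped for missing race is attached as
    ``result.attrs['n_dropped_missing_race']``.
    """
    missing = df[race_col].isna()
    out = df.loc[~missing].copy()
    out.attrs = dict(df.attrs)
    out[out_col] = recode_ingroup(
        out[d_col].to_numpy(dtype=float), out[race_col], reverse_groups
    )
    out.attrs["n_dropped_missing_race"] = int(missing.sum())
    return out
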