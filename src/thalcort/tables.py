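"""Printed anatomical/physiological parameter tables.

``MEMBRANE``: per-population leak and rest constants.  ``CONNECTIVITY_PCT``:
afferent synaptic connectivity percentages of the base state, rows =
postsynaptic population, columns = presynaptic.  The B6 afferent row repeats
B4's (the anatomical source does not document B6), and the B6->Py6 entry is
the ten-fold boosted value 13% (pre-boost 1.3%) that brings the Py6 mean
membrane potential down from an up-state near -20 mV to about -60 mV.
``SYNAPSE_COUNTS`` is the excerpt of the absolute synapse-count table used to
derive the cortical percentages (counts summed over all layers where the
synapses form).
"""

from __future__ import annotations

import pandas as pd

# population -> (kind, V_rest mV, g_lk uS/cm^2, E_lk mV); leak None = exogenous
MEMBRANE = {
    "TCR": ("excitatory", -65.0, 10.0, -55.0),
    "TRN": ("inhibitory", -85.0, 10.0, -72.5),
    "IN": ("inhibitory", -75.0, 10.0, -72.5),
    "Py4": ("excitatory", -65.0, 10.0, -55.0),
    "SS4": ("excitatory", -65.0, 10.0, -55.0),
    "Py6": ("excitatory", -65.0, 10.0, -55.0),
    "B4": ("inhibitory", -85.0, 10.0, -72.5),
    "B6": ("inhibitory", -85.0, 10.0, -72.5),
    "Ret": ("exogenous", -65.0, None, None),
    "Asy": ("exogenous", -65.0, None, None),
    "Sy": ("exogenous", -75.0, None, None),
}

# receptor kinetics: alpha (mM s)^-1, beta s^-1
ALPHA = {"AMPA": 100.0, "GABA_A": 100.0}
BETA = {"AMPA": 50.0, "GABA_A": 40.0}
E_REV_AMPA = 0.0
E_REV_GABA_INTER = -85.0
E_REV_GABA_RECURRENT = -75.0

# base-state afferent connectivity percentages: post -> {pre: percent}
CONNECTIVITY_PCT = {
    "TCR": {"TRN": 23.175, "IN": 7.725, "Py6": 62.0, "Ret": 7.1},
    "TRN": {"TCR": 35.0, "TRN": 20.0, "Py6": 50.0},
    "IN": {"IN": 23.6, "Py6": 29.0, "Ret": 47.4},
    "Py4": {"TCR": 1.2, "Py4": 4.0, "SS4": 11.6, "Py6": 22.5,
            "B4": 6.6, "B6": 6.6, "Asy": 27.3, "Sy": 5.5},
    "SS4": {"TCR": 1.6, "Py4": 3.9, "SS4": 14.1, "Py6": 29.4,
            "B4": 8.5, "B6": 8.5, "Asy": 23.8, "Sy": 5.2},
    "B4": {"TCR": 1.5, "Py4": 3.8, "SS4": 13.4, "Py6": 27.5,
           "B4": 9.8, "B6": 9.8, "Asy": 22.2, "Sy": 4.9},
    "B6": {"TCR": 1.5, "Py4": 3.8, "SS4": 13.4, "Py6": 27.5,
           "B4": 9.8, "B6": 9.8, "Asy": 22.2, "Sy": 4.9},
    "Py6": {"TCR": 0.8, "Py4": 4.3, "SS4": 4.6, "Py6": 16.0,
            "B4": 1.3, "B6": 13.0, "Asy": 45.8, "Sy": 12.9},
}

#: the ten-fold boosted entry and its pre-boost value (percent)
B6_PY6_BOOSTED = 13.0
B6_PY6_PREBOOST = 1.3

# provenance of each connectivity entry
_PRIOR = {"TCR", "TRN", "IN"}  # rows taken from earlier LGN work


def connectivity_provenance(pre: str, post: str) -> str:
    if post in _PRIOR:
        return "prior-work"
    if post == "B6" or (pre == "B6" and post != "Py6"):
        return "assumed-from-B4"
    if pre == "B6" and post == "Py6":
        return "boosted"
    return "derived"


# absolute synapse counts (excerpt): rows = postsynaptic, cols = presynaptic
_COUNT_COLS = ["Py2/3", "SS4(L4)", "SS4(L2/3)", "Py4", "Py5(L2/3)",
               "Py5(L5/6)", "Py6(L4)", "Py6(L5/6)", "X/Y", "Asy", "B2/3",
               "B4(B6)", "B5", "Sy", "db2/3"]
_COUNT_ROWS = {
    "B4(B6)": [188.3, 355.2, 121.7, 135.8, 36.4, 1.6, 980.2, 0.8, 52.2,
               793.1, 16.8, 349.1, 0.0, 173.1, 26.1],
    "Py4": [815.2, 583.6, 243.3, 282.5, 127.7, 4.5, 1602.4, 5.3, 84.9,
            1957.3, 57.0, 472.8, 2.6, 388.4, 75.7],
    "Py6(L4)": [709.8, 294.4, 131.1, 213.3, 154.1, 170.8, 711.0, 452.4, 54.7,
                2518.6, 20.6, 136.9, 26.6, 744.5, 24.1],
    "Py6(L5/6)": [449.4, 80.9, 83.0, 123.7, 58.9, 274.5, 160.6, 740.0, 37.1,
                  3406.8, 22.5, 23.4, 21.4, 917.5, 21.3],
    "SS4(L2/3)": [277.6, 562.2, 190.4, 212.3, 55.0, 2.5, 1551.2, 1.3, 82.6,
                  1255.8, 22.1, 462.0, 0.0, 273.8, 40.0],
    "SS4(L4)": [157.4, 687.8, 212.5, 236.7, 44.8, 3.1, 1895.3, 1.6, 101.2,
                1540.1, 10.9, 529.7, 0.0, 333.4, 37.1],
}


def synapse_counts() -> pd.DataFrame:
    """Absolute synapse-count excerpt as a DataFrame (rows postsynaptic)."""
    return pd.DataFrame.from_dict(
        _COUNT_ROWS, orient="index", columns=_COUNT_COLS
    )


def connectivity_frame() -> pd.DataFrame:
    """Base-state connectivity percentages as a post x pre DataFrame."""
    from .core import ALL_POPULATIONS, DYNAMIC_POPULATIONS

    df = pd.DataFrame(0.0, index=list(DYNAMIC_POPULATIONS),
                      columns=list(ALL_POPULATIONS))
    for post, row in CONNECTIVITY_PCT.items():
        for pre, pct in row.items():
            df.loc[post, pre] = pct
    return df
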