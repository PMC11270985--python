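"""Bundled reference datasets."""

from importlib import resources

import pandas as pd


def load_joint_effects() -> pd.DataFrame:
    """Published joint-effect estimates for clothianidin toxicity to
    *Gammarus pulex* under prochloraz co-exposure and warming.

    One row per (design, population, temperature °C, prochloraz µg/L):
    observed EC50 (µg/L), CA-predicted EC50 (µg/L) and the MDR under the
    concentration-addition, effect-addition and stress-addition models.
    Control rows (``control == 1``) carry only the observed EC50.
    """
    with resources.files(__package__).joinpath(
            "gammarus_joint_effects.csv").open() as fh:
        return pd.read_csv(fh)
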