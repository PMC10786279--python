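"""Shared analysis helpers for the test suite."""

import numpy as np

from digitpattern.profiles import (
    IntensityProfile,
    align_profiles,
    normalize_nfi,
    phase_offset,
    pick_landmarks,
)

PIXEL_UM = 1.243


def simulated_phase_offsets(state) -> dict:
    """Channel phase offsets of a simulated pattern, via the profile pipeline.

    Treats the final model state as a multi-channel section trace (GDF5 and
    NOG mRNA, pSMAD, free GDF5 protein), min-max normalizes, aligns on the
    two most distal GDF5-mRNA peaks and measures circular offsets relative
    to GDF5 mRNA over one landmark-frame wavelength.
    """
    prof = IntensityProfile(
        position=state.x / PIXEL_UM,
        channels={
            "GDF5": state.m_G,
            "NOG": state.m_N,
            "pSMAD": state.S,
            "GDF5prot": state.G,
        },
        specimen="simulated",
    )
    nfi = normalize_nfi(prof)
    marks = pick_landmarks(nfi, "GDF5")
    aligned = align_profiles([nfi], [marks], grid_n=201)
    spec = aligned.specimens()[0]
    values = aligned.values[spec]
    return {
        "m_N": phase_offset(values["GDF5"], values["NOG"], grid=aligned.grid),
        "S": phase_offset(values["GDF5"], values["pSMAD"], grid=aligned.grid),
        "G": phase_offset(values["GDF5prot"], values["pSMAD"], grid=aligned.grid),
    }
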