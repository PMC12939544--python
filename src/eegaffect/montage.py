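"""10-20 montage constants for the 8-channel analysis set.

The analysis uses the prefrontal (Fp1, Fp2), frontal (F3, F4, F7, F8) and
central (C3, C4) electrodes of the international 10-20 system. Odd indices
are left-hemisphere, even indices right-hemisphere; each left channel has a
homologous mirror on the right, which is what the alpha-asymmetry feature
compares.
"""

from __future__ import annotations

#: Canonical channel order of every standardized epoch.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
)

#: Left-hemisphere channels (odd 10-20 indices).
LEFT_CHANNELS: tuple[str, ...] = ("Fp1", "F3", "F7", "C3")

#: Right-hemisphere channels (even 10-20 indices).
RIGHT_CHANNELS: tuple[str, ...] = ("Fp2", "F4", "F8", "C4")

#: Homologous mirror map, both directions (Fp1 <-> Fp2, ...).
MIRROR: dict[str, str] = {
    "Fp1": "Fp2", "Fp2": "Fp1",
    "F3": "F4", "F4": "F3",
    "F7": "F8", "F8": "F7",
    "C3": "C4", "C4": "C3",
}

#: Channel order of the preprocessed 32-channel DEAP archives (Geneva order).
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "C4",
    "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
)

#: Standard epoch geometry: 7.5 s at 128 Hz.
FS: float = 128.0
EPOCH_SAMPLES: int = 960
EPOCH_SECONDS: float = 7.5
N_CHANNELS: int = 8
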