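"""Unit conventions shared across the package.

Everything runs in Å, fs and amu. Frequencies are reported in
wavenumbers (cm^-1): one cycle per femtosecond corresponds to
1/(c in cm/fs) = 33356.40952 cm^-1.
"""

#: cm^-1 per (cycle/fs)
CM1_PER_CYCLE_FS = 33356.40952


def cycles_fs_to_cm1(nu_cycles_per_fs: float) -> float:
    """Convert a frequency in cycles/fs to wavenumbers (cm^-1)."""
    return nu_cycles_per_fs * CM1_PER_CYCLE_FS


def cm1_to_cycles_fs(nu_cm1: float) -> float:
    """Convert wavenumbers (cm^-1) to cycles/fs."""
    return nu_cm1 / CM1_PER_CYCLE_FS
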