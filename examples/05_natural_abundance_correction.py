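"""Correct a raw mass spectrum for naturally occurring isotopes.

A TBDMS-derivatized aspartate-like fragment (C10 H20 N O2 Si2, four
skeleton carbons) is simulated: the true skeleton MDV is convolved with
the natural isotope pattern of every atom, then recovered by nonnegative
least squares against the correction matrix.
"""

import numpy as np

import emuflux as ef

comp = ef.FragmentComposition("Asp_TBDMS",
                              {"C": 10, "H": 20, "N": 1, "O": 2, "Si": 2},
                              skeleton_carbons=4)
K = ef.build_correction_matrix(comp, window=12)

skeleton = np.array([0.12, 0.45, 0.14, 0.27, 0.02])
raw = K.K @ skeleton
recovered = ef.correct_spectrum(raw, K)

np.set_printoptions(precision=4, suppress=True)
print("true skeleton MDV:  ", skeleton)
print("observed spectrum:  ", np.round(raw, 4))
print("corrected MDV:      ", recovered)
print(f"max recovery error: {np.max(np.abs(recovered - skeleton)):.2e}")
print("\nThe observed spectrum is smeared upward by ~9% per channel "
      "(mostly 29/30-Si and natural 13C); correction removes it exactly "
      "on noise-free data.")
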