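"""Shared numerical tolerance constants.

All orthogonality / reconstruction checks in the package use these two
values: ``ATOL`` for quantities that should vanish exactly (off-diagonal
inner products, filter-bank orthogonality defects) and ``RTOL`` for
relative errors on reconstructed data.
"""

ATOL = 1e-10
RTOL = 1e-8

SUPPORTED_BANDS = (2, 3, 4)
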