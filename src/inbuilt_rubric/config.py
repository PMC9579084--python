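"""Named numerical constants shared across the package.

Tolerances are deliberately centralized: the transform stage asserts exact
linear-algebra identities (orthonormality, rotation invariance) and the
values below are the single source of truth for those checks.
"""

#: Fidelity gate: minimum pre/post-orthogonalization correlation for a
#: meaningful column of the basis to be considered a reliable stand-in
#: for the concept it encodes.
FIDELITY_THRESHOLD: float = 0.80

#: Orthonormality tolerance for Gram-Schmidt output (max |Q'Q - I|).
GS_ORTHO_TOL: float = 1e-10

#: Residual norm below which a Gram-Schmidt column is declared degenerate
#: (linearly dependent on the columns processed before it).
GS_DEGENERATE_TOL: float = 1e-10

#: Rotation-invariance tolerance: pairwise cosines and norms of term
#: vectors must be preserved by a change of basis within this bound.
ROTATION_TOL: float = 1e-8

#: |cosine| above which the general-factor vector is considered collinear
#: with a concept vector and the bifactor basis is rejected.
COLLINEARITY_TOL: float = 0.999

#: Default minimum document frequency for vocabulary terms.  Terms in a
#: single document carry a global entropy weight of exactly 1 and can
#: dominate concept vectors, so they are excluded unless asked for.
MIN_DOC_FREQ_DEFAULT: int = 2

#: Fraction of out-of-vocabulary tokens above which a scored document is
#: flagged as unreliable (it is still scored, never dropped).
OOV_FLAG_THRESHOLD: float = 0.50

#: Lower bound for uniquenesses / residual variances during factor and
#: structural model optimization.
VARIANCE_FLOOR: float = 1e-6
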