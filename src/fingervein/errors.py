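"""Exception hierarchy for the finger-vein pipeline."""


class FingerVeinError(Exception):
    """Base class for all package errors."""


class ContractError(FingerVeinError, ValueError):
    """An argument violates a documented precondition."""


class ValidationError(FingerVeinError, ValueError):
    """Input data violates a structural invariant."""


class ManifestError(ValidationError):
    """A dataset manifest is malformed (duplicates, unknown labels, ...)."""


class DetectionError(FingerVeinError, RuntimeError):
    """Finger-region detection failed; the image is rejected."""


class UnreliableDPrimeWarning(UserWarning):
    """d-prime computed on a score distribution that fails a normality screen.

    d-prime summarizes class separation correctly only when both score
    distributions are approximately Gaussian; PRODUCT-rule fusion in
    particular produces heavily skewed authentic distributions.
    """
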