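"""Exception hierarchy shared across the package."""


class PhotoboError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PhotoboError, ValueError):
    """Invalid domain object or configuration."""


class SmilesParseError(PhotoboError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class DimensionError(PhotoboError, ValueError):
    """Mismatched vector/matrix dimensions."""


class LookupMissError(PhotoboError, KeyError):
    """A condition or entity id could not be resolved."""


class PSDError(PhotoboError, RuntimeError):
    """Kernel matrix not positive semi-definite even after jitter escalation."""

    def __init__(self, min_eigenvalue: float):
        self.min_eigenvalue = min_eigenvalue
        super().__init__(
            f"kernel matrix not PSD after jitter escalation "
            f"(minimum eigenvalue {min_eigenvalue:.3e})"
        )


class SpaceExhaustedError(PhotoboError, RuntimeError):
    """Every candidate in the discrete space has already been observed."""


class NotMeasuredError(PhotoboError, KeyError):
    """Replay oracle was queried for an id absent from the measured table."""

    def __init__(self, target_id: str):
        self.target_id = target_id
        super().__init__(f"target {target_id!r} was not measured in the replayed campaign")


class TableValidationError(PhotoboError, ValueError):
    """A results table failed strict-mode validation."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"results table rejected: {report}")
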