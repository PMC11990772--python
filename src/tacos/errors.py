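"""Exception hierarchy for tacos."""


class TacosError(Exception):
    """Base class for all tacos errors."""


class CoordinateMissingError(TacosError):
    """Raised when a slice file carries no spatial coordinates."""


class DuplicateIdentifierError(TacosError):
    """Raised when gene or spot identifiers are not unique."""


class EmptyGeneSetError(TacosError):
    """Raised when the intersection of per-slice HVG sets is empty."""


class InsufficientPointsError(TacosError):
    """Raised when a neighborhood computation has too few points."""


class DivergenceError(TacosError):
    """Raised when a training loss becomes non-finite.

    Carries the epoch and the name of the offending loss component.
    """

    def __init__(self, epoch: int, component: str):
        self.epoch = epoch
        self.component = component
        super().__init__(
            f"non-finite loss at epoch {epoch} in component '{component}'; "
            "try lowering the learning rate"
        )
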