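"""Exception hierarchy for plscv.

``PlscvError`` is the base for everything this package raises on purpose;
``UserInputError`` marks problems a caller can fix (bad shapes, bad config,
bad files) and maps to exit code 1 in the CLI.
"""


class PlscvError(Exception):
    """Base class for all plscv errors."""


class UserInputError(PlscvError, ValueError):
    """Invalid user-supplied data, parameters or configuration."""


class ComponentNullError(PlscvError):
    """A requested latent component is numerically null (rank deficiency).

    Carries the 1-based index of the failing component.
    """

    def __init__(self, component: int, detail: str = ""):
        self.component = component
        msg = f"component {component} is numerically null (score norm below tolerance)"
        if detail:
            msg = f"{msg}: {detail}"
        super().__init__(msg)


class RankDeficiencyError(PlscvError):
    """A loading matrix does not have full column rank."""


class IllConditionedError(PlscvError):
    """A matrix that must be inverted is singular or ill-conditioned."""
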