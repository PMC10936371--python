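"""Exception hierarchy for snapsole."""


class SnapsoleError(Exception):
    """Base class for all snapsole errors."""


class GeometryError(SnapsoleError):
    """Invalid arch geometry or material parameters."""


class NoSnapError(SnapsoleError):
    """The arch shape parameter is below the asymmetric-bifurcation threshold:
    there is no inverted configuration reachable by second-mode switching."""

    def __init__(self, Q: float, Q_threshold: float):
        self.Q = Q
        self.Q_threshold = Q_threshold
        super().__init__(
            f"no snap-through: Q={Q:.4g} is below the asymmetric-bifurcation "
            f"threshold Q={Q_threshold:.4g}"
        )


class NotSelfReturningError(SnapsoleError):
    """The released arch cannot return to the as-fabricated shape: the free
    oscillation energy lies below the inter-well barrier of the reduced
    potential (the switchback quartic has four real roots)."""


class IntegrationError(SnapsoleError):
    """Transient integration failed its accuracy check."""

    def __init__(self, message: str, suggested_dt: float | None = None):
        self.suggested_dt = suggested_dt
        super().__init__(message)


class DecodeError(SnapsoleError):
    """A pressure image could not be decoded against the colour legend."""


class ConfigError(SnapsoleError):
    """Invalid run configuration."""


class InfeasibleDesignError(SnapsoleError):
    """No arch geometry in the search bounds satisfies all constraints."""

    def __init__(self, message: str, report: dict | None = None):
        self.report = report or {}
        super().__init__(message)
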