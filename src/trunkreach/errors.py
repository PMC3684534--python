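"""Exception hierarchy shared by all trunkreach modules."""


class TrunkReachError(Exception):
    """Base class for all trunkreach errors."""


class InvalidParameterError(TrunkReachError, ValueError):
    """A scalar parameter violates its precondition (e.g. G < 1, T <= 0)."""


class InvariantError(TrunkReachError, ValueError):
    """A constructed object violates one of its declared invariants."""


class GridError(TrunkReachError, ValueError):
    """Time-grid construction or compatibility failure (dt does not divide T,
    non-uniform spacing, mismatched grids between series)."""


class UnreachableError(TrunkReachError, ValueError):
    """Requested hand position lies outside the arm's annular workspace."""


class SingularConfigurationError(TrunkReachError, ValueError):
    """Hand position lies on the workspace boundary (fully extended or folded)."""


class FrameError(TrunkReachError, ValueError):
    """Two paths expressed in different reference frames were combined."""
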