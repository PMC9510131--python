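"""Exception hierarchy.

Domain errors (subclasses of :class:`CmaError`) map to CLI exit code 1,
usage errors (:class:`UsageError`) to exit code 2.
"""


class CmaError(Exception):
    """Base class for all domain errors raised by this package."""


class UsageError(CmaError):
    """Invalid arguments or inconsistent inputs supplied by the caller."""


class ParseError(CmaError):
    """A structure file could not be parsed under the named format."""


class EmptySelectionError(CmaError):
    """A residue-range or chain selection matched nothing."""


class NoAxisError(CmaError):
    """No two-fold symmetry axis could be derived from the chain pair."""


class InfeasibleAssemblyError(CmaError):
    """No clash-free solution exists within the scanned search space.

    ``per_variant_arcs`` carries the feasible arcs of each variant for
    diagnosis when a dihedral intersection is empty.
    """

    def __init__(self, message, per_variant_arcs=None):
        super().__init__(message)
        self.per_variant_arcs = per_variant_arcs


class AnchorNotFoundError(CmaError):
    """A sequence-edit anchor motif is absent or at the wrong position."""


class AmbiguousAnchorError(CmaError):
    """An anchor motif occurs more than once and no position was given."""
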