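"""Exception hierarchy.

Every error raised by this package derives from :class:`TetrastabError`, so
callers can catch one type at a pipeline boundary.  Subclasses distinguish
*what kind* of contract was violated (file format, array shapes, atom
selection, cross-system consistency, ...), because the remedies differ.
"""


class TetrastabError(Exception):
    """Base class for all package errors."""


class FormatError(TetrastabError):
    """A file does not conform to its declared format."""


class DimensionError(TetrastabError):
    """Array/atom-count shapes disagree (e.g. trajectory vs. topology)."""


class SelectionError(TetrastabError):
    """An atom/residue selection resolved to nothing or to a missing target."""


class DegenerateGeometryError(TetrastabError):
    """A geometric operation received a degenerate configuration
    (coincident or collinear points) for which it is not defined."""


class AlignmentError(TetrastabError):
    """Two residue-labelled matrices cannot be compared because their
    label lists differ."""


class ConsistencyError(TetrastabError):
    """Inputs that must describe the same system/arrangements disagree."""


class RangeError(TetrastabError):
    """An empty or out-of-bounds frame range."""


class MissingControlError(TetrastabError):
    """A required control group (empty-vector wells, WT reference) is absent."""


class SampleSizeError(TetrastabError):
    """A statistical procedure received fewer replicates than it requires."""


class ConstructionError(TetrastabError):
    """A synthetic-geometry spec is geometrically impossible."""


class ConfigError(TetrastabError):
    """Invalid run configuration.  Carries the full list of problems so a
    user can fix everything in one pass."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
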