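"""Exception hierarchy for the platefit package."""


class PlatefitError(Exception):
    """Base class for all platefit errors."""


class MeshFormatError(PlatefitError):
    """A mesh file could not be parsed as the named format."""


class MeshValidationError(PlatefitError):
    """Mesh geometry violates a structural invariant (bad indices, NaNs,
    degenerate-only geometry, ...)."""


class NotWatertightError(PlatefitError):
    """An operation requiring a closed orientable surface received an open mesh."""


class EmptySectionError(PlatefitError):
    """A cutting plane does not intersect the mesh."""


class OpenLoopError(PlatefitError):
    """A section polyline is not closed."""


class LandmarkError(PlatefitError):
    """A required anatomical landmark is missing or inconsistently ordered."""


class DegenerateTestError(PlatefitError):
    """A statistical test is undefined for the given data (constant input,
    zero expected cell count, ...)."""


class PlateSelectionError(PlatefitError):
    """No available plate length satisfies the proximal-tip clearance rule."""


class UnconvergedPositioningError(PlatefitError):
    """Fit measurement was requested for a plate placement that did not
    satisfy the positioning constraints."""


class CollinearPointsError(PlatefitError):
    """Circle fitting received (near-)collinear points."""
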