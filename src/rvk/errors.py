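"""Exception hierarchy.

All package errors derive from :class:`RVKError` so callers can catch one base.
The split mirrors the failure modes of the pipeline: malformed bundles
(schema/structure/data), bad parameters, geometric degeneracy, mesh topology,
Baseline/TRA correspondence, and degenerate statistical tests.
"""


class RVKError(Exception):
    """Base class for all rvk errors."""


class SchemaError(RVKError):
    """A bundle header, layout or channel table violates the documented schema."""


class StructuralError(RVKError):
    """Channels/arrays have inconsistent lengths or shapes."""


class DataError(RVKError):
    """Channel values are invalid (non-finite, out of range), with location."""


class ParameterError(RVKError, ValueError):
    """An argument is outside its documented domain."""


class DegeneracyError(RVKError):
    """Geometric input is degenerate (collinear points, coplanar hull, zero-area face)."""


class TopologyError(RVKError):
    """Mesh is not an orientable manifold-with-boundary."""


class CorrespondenceError(RVKError):
    """Baseline/TRA inputs do not share labels or connectivity."""


class CycleError(RVKError):
    """Cardiac-cycle segmentation or averaging cannot proceed."""


class PairingError(RVKError):
    """Paired recordings cannot be matched by id."""


class DegenerateTestError(RVKError):
    """A statistical test is undefined on the given sample (e.g. zero-variance differences)."""
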