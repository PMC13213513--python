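"""Exception hierarchy for the preorganization-analysis pipeline."""


class PreorgError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(PreorgError):
    """An atom or molecule cannot be resolved against the topology sidecar."""


class MalformedInputError(PreorgError):
    """A coordinate file violates the multi-frame contract."""


class GeometryError(PreorgError):
    """Degenerate geometry (collinear ring, coincident centroids, ...)."""


class PlacementError(PreorgError):
    """The synthetic generator cannot place molecules without overlap."""


class SelectionError(PreorgError):
    """A population selection is impossible (e.g. no modifier present)."""


class ContractError(PreorgError):
    """Mismatched axes, non-regular grids, or other interface violations."""
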