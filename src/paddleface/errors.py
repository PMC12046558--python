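"""Exception hierarchy for paddleface."""


class PaddlefaceError(Exception):
    """Base class for all package-specific errors."""


class TrajectoryError(PaddlefaceError):
    """Malformed or inconsistent multi-frame structure input."""


class TopologyError(PaddlefaceError):
    """Invalid or inconsistent topology-map annotation."""


class GeometryError(PaddlefaceError):
    """Degenerate geometry (collinear torsion, zero-normal plane, ...)."""


class AnalysisError(PaddlefaceError):
    """Not enough usable data for a statistical operation."""


class InfeasibleSpecError(PaddlefaceError):
    """A synthetic generator spec that cannot be realized geometrically."""
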