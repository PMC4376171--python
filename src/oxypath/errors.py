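"""Exception hierarchy."""


class OxypathError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(OxypathError):
    """Topology file unreadable, truncated, or structurally invalid."""


class TrajectoryError(OxypathError):
    """Coordinate file unreadable, corrupt, or inconsistent with the topology."""


class AnnotationError(OxypathError):
    """Helix/cavity annotation fails to parse or validate."""


class ScriptError(OxypathError):
    """A synthetic event script is inconsistent with its toy system."""


class ParameterError(OxypathError):
    """An analysis or simulation parameter is out of its documented range."""


class SimulationError(OxypathError):
    """Numerical failure (divergence, non-finite force) in the toy simulator."""
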