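"""Exception hierarchy shared across the package."""


class AllodynError(Exception):
    """Base class for all allodyn errors."""


class InvalidSpecError(AllodynError, ValueError):
    """A synthetic-trajectory specification violates its invariants."""


class FormatError(AllodynError, ValueError):
    """A structure or trajectory file could not be parsed."""


class EmptyInputError(AllodynError, ValueError):
    """An input contained no usable atoms/frames/values."""


class TopologyMismatchError(AllodynError, ValueError):
    """Trajectory and topology disagree on atom or residue count."""


class SelectionError(AllodynError, ValueError):
    """An atom/residue selection is ambiguous or empty."""


class DegenerateFitError(AllodynError, ValueError):
    """Too few or collinear atoms for a least-squares superposition."""


class MetricError(AllodynError, ValueError):
    """A metric is undefined for the given input (e.g. single frame)."""


class GraphError(AllodynError, ValueError):
    """Invalid residue-graph construction or centrality input."""


class ConfigError(AllodynError, ValueError):
    """A pipeline run configuration is invalid."""


class DataError(AllodynError, ValueError):
    """Input data files are missing or inconsistent at pipeline level."""
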