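"""Exception hierarchy shared across the pipeline."""


class GraphBindError(Exception):
    """Base class for all package errors."""


class ChainLookupError(GraphBindError, KeyError):
    """Requested chain id not present in the structure file."""


class EmptyChainError(GraphBindError, ValueError):
    """No residue in the chain carries a C-alpha atom."""


class LabelingError(GraphBindError, ValueError):
    """Label sidecar does not match the residues of the chain."""


class ShapeError(GraphBindError, ValueError):
    """Array dimensions inconsistent with the graph or model contract."""


class ProviderError(GraphBindError, RuntimeError):
    """An embedding provider backend is unavailable or misconfigured."""


class DegenerateInputError(GraphBindError, ValueError):
    """Input is structurally valid but degenerate for the operation
    (e.g. a single-class training set handed to the oversampler)."""
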