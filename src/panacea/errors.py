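"""Exception hierarchy for panacea."""


class PanaceaError(Exception):
    """Base class for all panacea errors."""


class ParseError(PanaceaError):
    """An input table could not be parsed (malformed row, bad column)."""


class EmptyNetworkError(PanaceaError):
    """No edges survive confidence filtering, or no valid rows exist."""


class NoEdgesError(PanaceaError):
    """The extended network has no edges, so there is nothing to propagate over."""


class NoPriorSignalError(PanaceaError):
    """The prior vector Y is identically zero: propagation would return all zeros."""
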