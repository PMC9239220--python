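"""Exception hierarchy for model, data and solver failures."""


class YmcfluxError(Exception):
    """Base class for all package-specific errors."""


class GprParseError(YmcfluxError):
    """Malformed gene-protein-reaction rule text (position reported in message)."""


class ModelSchemaError(YmcfluxError):
    """Structurally invalid model document (missing field, duplicate or unknown id)."""


class InfeasibleError(YmcfluxError):
    """The optimization problem has no feasible point under the given constraints."""


class UnboundedError(YmcfluxError):
    """The optimization objective is unbounded in the requested direction."""


class OmicsError(YmcfluxError):
    """Invalid omics/differential table contents (location reported in message)."""
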