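"""Exception hierarchy shared across the package."""


class FuncTreeError(Exception):
    """Base class for all errors raised by this package."""


class HierarchyError(FuncTreeError):
    """Invalid membership tables or a malformed Functional Tree."""


class SchemaError(FuncTreeError):
    """Tree JSON document fails schema or layer-order validation."""


class ParseError(FuncTreeError):
    """Malformed delimited input (node-value lists, gene lists, profiles)."""


class StatsError(FuncTreeError):
    """Invalid input to a statistical routine."""


class RenderError(FuncTreeError):
    """Invalid layout or value-scaling request."""
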