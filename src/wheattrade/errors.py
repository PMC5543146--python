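"""Exception types shared across the package."""


class WheatTradeError(Exception):
    """Base class for package errors."""


class SelfLoopError(WheatTradeError, ValueError):
    """A country attempted to trade with itself."""


class DuplicateEdgeError(WheatTradeError, ValueError):
    """The directed trade partnership already exists."""


class MissingEdgeError(WheatTradeError, KeyError):
    """The directed trade partnership does not exist."""


class UndefinedMetricError(WheatTradeError, ArithmeticError):
    """A network metric is undefined on this network (degenerate input).

    Raised explicitly instead of returning a silent zero; callers that
    tabulate metric records convert it to NaN.
    """


class GrowthStallError(WheatTradeError, RuntimeError):
    """The growth loop exhausted its attempt budget without adding an edge."""


class ConfigError(WheatTradeError, ValueError):
    """Invalid experiment configuration or mismatched inputs."""
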