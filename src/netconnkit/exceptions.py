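"""Exception types shared across the toolkit."""


class NetconnkitError(Exception):
    """Base class for all toolkit errors."""


class UndefinedMetricError(NetconnkitError):
    """A graph metric is mathematically undefined for this input.

    Raised instead of fabricating a value, e.g. assortativity on a regular
    graph (zero degree variance over edge endpoints), synchronizability of a
    disconnected graph, or the hierarchy exponent when fewer than two nodes
    carry both degree >= 2 and positive clustering.
    """


class InvalidDesignError(NetconnkitError):
    """A statistical design is unusable (rank-deficient, too few subjects)."""
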