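"""Exception hierarchy.

All package-specific failures derive from :class:`MetricsError` so callers
can catch one base class at API boundaries (the CLI maps them to nonzero
exit codes).
"""


class MetricsError(Exception):
    """Base class for all metriscore errors."""


class SchemaError(MetricsError):
    """A file or table does not match the expected layout/columns/values."""


class IntegrityError(MetricsError):
    """An instrument table violates a structural invariant (cardinality,
    weight conservation, conditionality tags)."""


class ProfileError(MetricsError):
    """An applicability profile violates a hard invariant."""


class ConsistencyError(MetricsError):
    """Assessment statuses contradict the applicability resolved from the
    study's profile."""


class DomainError(MetricsError):
    """A numeric argument is outside its valid domain."""


class FlowError(MetricsError):
    """Round-to-round Delphi bookkeeping violated (an already-resolved item
    re-voted, or a pending item missing from the next round)."""


class FeasibilityError(MetricsError):
    """Requested synthetic data cannot exist (e.g. a median-rank target
    vector no set of permutations can realize)."""


class CertificationError(MetricsError):
    """No median-rank configuration reproduces the instrument's weights."""
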