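"""Typed exceptions shared across the fieldsync toolkit.

Every rejected operation raises a subclass of :class:`FieldSyncError` so
callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class FieldSyncError(Exception):
    """Base class for all fieldsync errors."""


class UnknownEntityTypeError(FieldSyncError):
    """An entity type outside the documented enumeration."""


class EntityNotFoundError(FieldSyncError):
    """The referenced entity id is not in the store."""


class EntryNotFoundError(FieldSyncError):
    """The referenced (entity, attribute) entry is not in the store."""


class InvalidAttributeError(FieldSyncError):
    """Empty or reserved attribute name used where not permitted."""


class ValueTypeError(FieldSyncError):
    """A value that cannot be represented as a typed attribute value."""


class VersionConflictError(FieldSyncError):
    """An operation would make an entry's version decrease."""


class GatingError(FieldSyncError):
    """A field-protocol eligibility rule rejected the record.

    Examples: weighing an individual marked absent, or recording a
    pregnancy for a male or a female of 10 months or younger.
    """


class LifecycleError(FieldSyncError):
    """Operation invalid for the current session/follow state."""


class DuplicateError(FieldSyncError):
    """Duplicate pack name, minute index, or open session."""


class TransportError(FieldSyncError):
    """The hub could not be reached or the transfer was interrupted."""


class MalformedMessageError(FieldSyncError):
    """A sync message missing required fields; rejected with no state change."""


class ExportError(FieldSyncError):
    """Invalid export specification or unwritable destination."""


class ScenarioError(FieldSyncError):
    """Malformed synthetic scenario script or degenerate population spec."""
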