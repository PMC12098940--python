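"""Exception hierarchy.

Every error raised deliberately by this package derives from :class:`ScsqlError`,
so callers can catch one type. Engine-level errors (``sqlite3.*``) are wrapped
where the package adds context (e.g. the offending statement) and propagate
otherwise.
"""


class ScsqlError(Exception):
    """Base class for all package errors."""


class InvalidIdentifierError(ScsqlError, ValueError):
    """A raw name cannot be turned into a database identifier (e.g. empty)."""


class InconsistentBundleError(ScsqlError, ValueError):
    """Layer dimensions of a dataset bundle disagree (X rows vs obs, X cols vs var)."""


class SerializationError(ScsqlError, ValueError):
    """A value in the unstructured-metadata layer cannot be serialized."""


class MissingTableError(ScsqlError, LookupError):
    """A required table or view does not exist in the database."""


class MissingColumnError(ScsqlError, LookupError):
    """A referenced column does not exist; carries original/sanitized names."""


class StaleHandleError(ScsqlError, RuntimeError):
    """Operation attempted on a closed database handle."""


class ReadOnlyError(ScsqlError, PermissionError):
    """Mutation attempted through a read-only handle."""


class NotSelectError(ScsqlError, ValueError):
    """`query()` received a non-SELECT statement; use update/delete/query_raw."""


class QueryExecutionError(ScsqlError, RuntimeError):
    """Engine error during `query_raw`; carries the offending statement."""

    def __init__(self, message: str, statement: str):
        super().__init__(f"{message}\nstatement: {statement}")
        self.statement = statement


class OrderingContractError(ScsqlError, RuntimeError):
    """A preprocessing step was invoked before its prerequisite (e.g. normalize
    before total counts); the message names the step to run first."""


class DomainError(ScsqlError, ValueError):
    """A value outside the mathematical domain of an operation (e.g. a negative
    expression value passed to a log transform); names the cell and gene."""


class DegenerateInputError(ScsqlError, ValueError):
    """Input carries no usable signal (e.g. only zero-variance genes for PCA)."""


class InsufficientCellsError(ScsqlError, ValueError):
    """A group has too few cells for the requested statistic."""


class NotConfiguredError(ScsqlError, RuntimeError):
    """A pluggable delegate (embedding / clustering) was not supplied."""


class PairingError(ScsqlError, ValueError):
    """Benchmark results for two methods do not form a matched paired design."""


class BenchmarkIntegrityError(ScsqlError, RuntimeError):
    """A benchmarked query returned a result that differs from the dense
    oracle; timings are refused for wrong answers."""


class OverwriteError(ScsqlError, FileExistsError):
    """Destination database file exists and overwrite was not requested."""
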