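"""Exception hierarchy.

Every data-facing failure mode carries a stable ``code`` string so that CLI
users and run reports can refer to it without parsing messages.
"""


class PpigcfError(Exception):
    """Base class; ``code`` is a stable machine-readable identifier."""

    code = "ERROR"

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class MalformedTableError(PpigcfError):
    code = "MALFORMED_TABLE"


class DuplicateGeneError(PpigcfError):
    code = "DUPLICATE_GENE"


class NonNumericCellError(PpigcfError):
    code = "NON_NUMERIC_CELL"


class UnknownSampleError(PpigcfError):
    code = "UNKNOWN_SAMPLE"


class NotTwoClassesError(PpigcfError):
    code = "NOT_TWO_CLASSES"


class BadAspectError(PpigcfError):
    code = "BAD_ASPECT"


class BadGoIdError(PpigcfError):
    code = "BAD_GO_ID"


class CycleDetectedError(PpigcfError):
    code = "CYCLE_DETECTED"


class MissingRootError(PpigcfError):
    code = "MISSING_ROOT"


class IOFailureError(PpigcfError):
    code = "IO_FAILURE"


class EmptyGroupsError(PpigcfError):
    code = "EMPTY_GROUPS"


class TooFewSamplesError(PpigcfError):
    code = "TOO_FEW_SAMPLES"


class ZeroGrandMeanError(PpigcfError):
    code = "ZERO_GRAND_MEAN"


class GeneNotInGraphError(PpigcfError):
    code = "GENE_NOT_IN_GRAPH"


class BadLambdaError(PpigcfError):
    code = "BAD_LAMBDA"


class NoDepthError(PpigcfError):
    code = "NO_DEPTH"


class BadConfigError(PpigcfError):
    code = "BAD_CONFIG"


class ConfigInvalidError(PpigcfError):
    code = "CONFIG_INVALID"


class EmptyClassError(PpigcfError):
    code = "EMPTY_CLASS"


class FoldTooSmallError(PpigcfError):
    code = "FOLD_TOO_SMALL"


class StageInputMissingError(PpigcfError):
    code = "STAGE_INPUT_MISSING"
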