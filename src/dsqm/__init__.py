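"""dsqm: docking-score quantitative matrices for MHC class II binding prediction.

Normalizes docking free binding energies into position-specific
quantitative matrices, scores peptide windows under position-subset
models, identifies binding cores, and benchmarks sensitivity at top-k%
cut-offs.  Ships the two 9-mer quantitative matrices for the human
class II allele HLA-DP2.
"""

from .errors import (
    ConfigurationError,
    DegenerateScopeError,
    DsqmError,
    FbeFormatError,
    MatrixFormatError,
    MatrixLookupError,
    ModelParseError,
    TestSetError,
)
from .matrices import (
    ALL_POSITIONS_13,
    AMINO_ACIDS,
    BUILTIN_MATRICES,
    CORE_POSITIONS,
    QuantMatrix,
    builtin_matrix,
    matrix_correlation,
    read_matrix,
    write_matrix,
)
from .normalization import FbeTable, normalize, partition_binders
from .scoring import (
    PeptideWindow,
    PositionModel,
    WindowScore,
    enumerate_windows,
    identify_core,
    parse_model,
    scan_protein,
    score_window,
)
from .evaluation import (
    DEFAULT_THRESHOLDS,
    KnownBinder,
    SensitivityResult,
    TestProtein,
    TestSet,
    load_testset,
    matches_binder,
    select_top,
    sensitivity,
)
from .simulate import (
    FbeSimConfig,
    TestSetSimConfig,
    gen_fbe_table,
    gen_testset,
    shuffle_matrix,
)

__version__ = "1.0.0"

__all__ = [
    "ALL_POSITIONS_13",
    "AMINO_ACIDS",
    "BUILTIN_MATRICES",
    "CORE_POSITIONS",
    "ConfigurationError",
    "DEFAULT_THRESHOLDS",
    "DegenerateScopeError",
    "DsqmError",
    "FbeFormatError",
    "FbeSimConfig",
    "FbeTable",
    "KnownBinder",
    "MatrixFormatError",
    "MatrixLookupError",
    "ModelParseError",
    "PeptideWindow",
    "PositionModel",
    "QuantMatrix",
    "SensitivityResult",
    "TestProtein",
    "TestSet",
    "TestSetError",
    "TestSetSimConfig",
    "WindowScore",
    "builtin_matrix",
    "enumerate_windows",
    "gen_fbe_table",
    "gen_testset",
    "identify_core",
    "load_testset",
    "matches_binder",
    "matrix_correlation",
    "normalize",
    "parse_model",
    "partition_binders",
    "read_matrix",
    "scan_protein",
    "score_window",
    "select_top",
    "sensitivity",
    "shuffle_matrix",
    "write_matrix",
]
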