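"""Exception hierarchy shared by all pipeline stages.

Each CLI-visible failure mode gets its own class so the command-line
front end can map it to a distinct exit code.
"""


class PipelineError(Exception):
    """Base class for all helixbridge errors."""

    exit_code = 1


class FormatError(PipelineError):
    """Input file could not be parsed in the expected format."""

    exit_code = 4


class EmptyInputError(PipelineError):
    """An input contained no usable records (e.g. a PDB with no atoms)."""

    exit_code = 5


class TopologyError(PipelineError):
    """Trajectory and topology disagree (atom-count mismatch etc.)."""

    exit_code = 4


class EmptyAnalysisError(PipelineError):
    """No frames left to analyse, e.g. the equilibration cut removed everything."""

    exit_code = 5


class UnsupportedResidueError(PipelineError):
    """Residue type has no defined charged side-chain atom set."""

    exit_code = 3


class UnusableResidueError(PipelineError):
    """Residue is of a supported type but side-chain atoms are missing."""

    exit_code = 3


class InsufficientDataError(PipelineError):
    """Too few points/residues/atoms for the requested fit."""

    exit_code = 5


class FitError(PipelineError):
    """Degenerate geometry defeated a least-squares fit."""

    exit_code = 1


class ConfigurationError(PipelineError):
    """Analysis configuration is inconsistent with the inputs."""

    exit_code = 3


class DegenerateTestError(PipelineError):
    """A statistical test is undefined for the given samples."""

    exit_code = 1
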