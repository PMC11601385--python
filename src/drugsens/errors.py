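"""Exception hierarchy shared across the package."""


class DrugSensError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DrugSensError):
    """A parameter or configuration value is invalid."""


class InputError(DrugSensError):
    """Input data violate a precondition (shape, range, missing values)."""


class MappingError(DrugSensError):
    """Conflicting entity mappings across sources."""


class ChemParseError(DrugSensError):
    """A SMILES string could not be parsed."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class TrainingDivergenceError(DrugSensError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class FileFormatError(DrugSensError):
    """A file does not conform to the expected dialect."""
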