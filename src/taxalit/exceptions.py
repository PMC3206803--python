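"""Exception hierarchy for taxalit."""


class TaxalitError(Exception):
    """Base class for all taxalit errors."""


class SchemaError(TaxalitError):
    """An input table is missing required columns or has a malformed layout."""


class IntegrityError(TaxalitError):
    """Referential integrity violated (e.g. a synonym pointing nowhere)."""


class TaxonLookupError(TaxalitError, KeyError):
    """An unknown taxon identifier was requested."""


class RankError(TaxalitError):
    """An operation received a taxon of an inadmissible rank."""


class UndefinedDiversityError(TaxalitError):
    """A diversity statistic is undefined for the given input (e.g. S < 2)."""


class ConfigurationError(TaxalitError):
    """Invalid configuration (bad bins, impossible tree shape, bad rates)."""
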