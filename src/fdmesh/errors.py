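"""Exception hierarchy shared by the fdmesh modules."""


class FdmeshError(Exception):
    """Base class for all fdmesh errors."""


class GeometryError(FdmeshError, ValueError):
    """A geometric quantity is outside its physical domain."""


class ConfigurationError(FdmeshError, ValueError):
    """A device specification or run configuration is invalid."""


class CenterlineParseError(FdmeshError, ValueError):
    """A centerline file violates the expected schema."""


class DeploymentError(FdmeshError, RuntimeError):
    """The device could not be placed in the vessel."""


class CohortSchemaError(FdmeshError, ValueError):
    """A cohort table violates the expected schema."""
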