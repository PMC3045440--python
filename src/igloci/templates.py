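"""Bundled synthetic constant-domain protein templates.

These are SYNTHETIC stand-ins for real mammalian constant-region domain
proteins: fixed random amino-acid strings with realistic lengths, used so
the test suite and the locus simulator need no external downloads. They
carry the exon roster of each isotype (a heavy mu gene has four CH plus
two transmembrane exons; a gamma gene has three CH plus two TM exons —
the hinge, which real gamma genes encode on a separate poorly conserved
exon, is deliberately not modeled). For real genomes, users supply real
domain templates in protein FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IsotypeTemplate:
    """An isotype's expected exon roster with one protein template per exon."""

    isotype: str
    exons: tuple[tuple[str, str], ...]  # (role, protein) in genomic order

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(role for role, _ in self.exons)

    def protein(self, role: str) -> str:
        for r, p in self.exons:
            if r == role:
                return p
        raise KeyError(role)


_SYNTHETIC_TEMPLATES: dict[str, dict[str, str]] = {
    "mu": {
        "CH1": "FVKDVMSDEAQCTECKYNTHALPVVTTEGNPFYPDMMFEATVNVSSLAAKFIECVMQEATFELKGKFNKLKFRPQIECMRGAQKDLTKKRVDAQLRDKQN",
        "CH2": "EMIFQSLIFGGLATSVDSSRQHDIRLNQWGWIHIWWGINDWNEKDKGECKQMLSGKMGILDWKPRPVYSDSSQNPVWYSNYQPDCRGWMWKQAVHCHHDM",
        "CH3": "IISAPPGAAQNNWDAPPRSMHSCADVQGARNCKTPLQFPMFDGCCEKQVYHTGVPGMFLSCPPEMPSWMALHMYNMLPAPCWIGGPWRFFPCWCDFGISF",
        "CH4": "NAAMASTMPFVHASGDPFRSPDALEVRDGGERPGIGVFTKNDPYVRYWASNMMWTGSCPFWVVDLFRIPKTQNCTQDHWCSPHRCGYGYKHKPDYTKWQQ",
        "TM1": "VTATLDCRQVCSHMINSWDSTHQGETPKWWVGRKIAPCTQ",
        "TM2": "ECQPTEVYYEDVYHMKYAEFWRYDQSEKWNVKMARC",
    },
    "gamma": {
        "CH1": "PAMFPFDEEIHDTMMMVRQYSCLLLHSMHAEMYPRACACEGWPCKCHGKFIWVNNIEFMWSTNYPTCRCKQHHCPETQNSCKITRVDWAVLGSNVRLKKH",
        "CH2": "KMMMDKEMQHGFRPCSWWFASVQCTWTDCMIYNMEPQAFEILTVVCINLARSVQVEMEIQCTGIAPFSGYYRWLEKFPAHTATWWYEPSDNEPAAPVCCH",
        "CH3": "WNNVHQEPPDGFMQAVTMRMWDPGNVSNQACCDQCRLRMWFSMSHYNTKGYWVFLPNNRWPPNFGKSLKEKRRFIALVGHSVSWVQWEKHSSENPFLDFK",
        "TM1": "PKAWTSSYFTEICDYIHMGDTAIWWAYILDVPFVMNPYIE",
        "TM2": "SFDLNTKDGQGPWWHRPRVHAYKDETGHCPSLCWVQ",
    },
    "delta": {
        "CH1": "PGLAVCEVWKRKWMFQYKIHFTWDERQRNMDFNDFGWVVIHDHSVYKCMVYIRMIFGFSNRHFLNGGKHSTQAPQDAWHGSYELSYNDHSHCEHSSNGNN",
        "CH2": "HTTDQERGMVADRLPYKPESRMSFRHRDMVIWWCQIFTTTMESDSTYPGMGVCQRIQPMCITSAFGGQIKIHRIFWSMYKWYTEMVVTFGNYYAVVVCVK",
        "CH3": "CDLRLQWLGYPDWHLYDGPCRDHVLIKMDDYVHKLHHYNCVHLGPRYSSLALSADQYSCFEQMHTRKCALNEHTENRCQAKDFSHDAPRQVTGGECMYLY",
        "TM1": "SIIYVMWGGEEWPQKDNMPEFWDASHPYFWGRSNWELDCK",
        "TM2": "HHARDRKGVQCDFRKDRWRIKAYKYVNPKEEYYCQI",
    },
    "c_kappa": {
        "C-domain": "NDAYQWQWWVQMQGFQSGFIFMKDFYMKKYEKKPVIQISVEHNVVETVQQWESSGKAIGMDIEPTPGMHIVPSIAERIMHDVQICLGHFWACVMPANTCTFILYSF",
    },
    "c_lambda": {
        "C-domain": "KGMNVTAIYCCLTNGHDCDSRTSTLGIVEEDPIRRLRVVSCMLKTDYNPYQADIWAQKPQPIGACADSQASPSGTMVPQMPQSIWAACCDMCMSEMLQESCSLQ",
    },
}

_ROSTER_ORDER: dict[str, tuple[str, ...]] = {
    "mu": ("CH1", "CH2", "CH3", "CH4", "TM1", "TM2"),
    "gamma": ("CH1", "CH2", "CH3", "TM1", "TM2"),  # hinge intentionally absent
    "delta": ("CH1", "CH2", "CH3", "TM1", "TM2"),
    "c_kappa": ("C-domain",),
    "c_lambda": ("C-domain",),
}


def default_templates() -> dict[str, IsotypeTemplate]:
    """The bundled synthetic isotype templates, keyed by isotype name."""
    return {
        iso: IsotypeTemplate(
            iso, tuple((role, _SYNTHETIC_TEMPLATES[iso][role]) for role in roles)
        )
        for iso, roles in _ROSTER_ORDER.items()
    }


def load_templates_fasta(path: str) -> dict[str, IsotypeTemplate]:
    """Load isotype templates from protein FASTA with ``>isotype|role`` headers.

    Roles appear in genomic order of first occurrence per isotype.
    """
    from Bio import SeqIO

    by_iso: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"template header {rec.id!r} must be 'isotype|role'")
        iso, role = rec.id.split("|", 1)
        by_iso.setdefault(iso, []).append((role, str(rec.seq).upper()))
    return {iso: IsotypeTemplate(iso, tuple(exons)) for iso, exons in by_iso.items()}
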