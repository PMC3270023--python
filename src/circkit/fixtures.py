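"""Bundled reference fixtures.

Currently one record: the published 481-nt northern-blot probe
complementary to the MAN1A2 5-2 backsplice junction, useful as a known
circle-derived sequence in tests and demonstrations.
"""

from importlib import resources

from Bio import SeqIO


def man1a2_probe() -> str:
    """The 481-nt MAN1A2 5-2 junction probe sequence."""
    path = resources.files("circkit") / "data" / "man1a2_probe.fasta"
    with resources.as_file(path) as fp:
        record = next(SeqIO.parse(str(fp), "fasta"))
    return str(record.seq)
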