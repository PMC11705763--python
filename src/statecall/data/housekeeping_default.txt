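# Default housekeeping gene list (HGNC symbols).
# Widely used constitutively expressed genes drawn from standard
# RT-qPCR reference panels and stably expressed gene surveys.
# Override with --housekeeping for matrices keyed by other identifiers.
ACTB
GAPDH
B2M
TUBB
HPRT1
RPL13A
RPLP0
TBP
PGK1
PPIA
GUSB
SDHA
YWHAZ
UBC
HMBS
TFRC
RPS18
RPL32
EEF1A1
PSMB2
PSMB4
RAB7A
REEP5
SNRPD3
VCP
VPS29
EMC7
GPI
CHMP2A
C1orf43
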