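# Amino-acid composition of UniProtKB/Swiss-Prot (percent of residues).
# Values are the published release statistics; they sum to 99.92% as
# printed and are renormalized to 1 on load.
# letter	percent
A	8.26
R	5.53
N	4.06
D	5.46
C	1.37
Q	3.93
E	6.74
G	7.08
H	2.27
I	5.93
L	9.65
K	5.82
M	2.41
F	3.86
P	4.72
S	6.61
T	5.35
W	1.09
Y	2.92
V	6.86
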