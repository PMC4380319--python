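"""Amino-acid scale sets for physicochemical conservation features.

The default set has 19 mutually decorrelated scales, mirroring the shape of
the VARIMAX-derived AAIndex factor scales commonly used for this purpose.
It is a synthetic stand-in, not the published factor solution: scales 1, 2,
3, 4, 7 and 8 are standardized versions of well-known published property
scales (Kyte-Doolittle hydropathy, Chou-Fasman helix propensity, residue
mass, proteome amino-acid composition, isoelectric point and Chou-Fasman
sheet propensity, matching the properties conventionally associated with
those scale indices); the remaining 13 are fixed pseudorandom scales
orthogonalised against the others.  Any user table with the same shape
(20 amino-acid rows x K value columns) can be loaded with
:func:`varinterp.io.read_scales` and used instead.
"""

from __future__ import annotations

import io as _io

from .io import ScaleSet, read_scales

_DEFAULT_SCALES_TSV = """\
aa	scale_1	scale_2	scale_3	scale_4	scale_5	scale_6	scale_7	scale_8	scale_9	scale_10	scale_11	scale_12	scale_13	scale_14	scale_15	scale_16	scale_17	scale_18	scale_19
A	0.7866	1.5330	-1.5891	1.4693	-1.4517	-1.5491	-0.0142	-0.5530	0.3122	-0.9605	-0.2605	0.7802	0.2847	-0.9653	-0.5011	1.1122	-1.4656	-2.2536	1.1553
C	1.0270	-1.0950	-0.5234	-1.6359	1.3469	-1.0015	-0.5535	0.4499	-0.4810	0.4004	1.9495	0.4911	-0.7901	-0.7122	-0.3124	-1.1116	0.3667	-1.3327	0.4831
D	-1.0339	0.0365	-0.1262	0.2056	0.5619	0.7039	-1.8872	-1.3609	0.4916	-0.5436	0.4377	-0.5903	-0.3433	1.4655	-0.4084	2.1449	1.6959	-1.0384	-0.9373
E	-1.0339	1.8615	0.3402	0.7923	-0.5074	0.8984	-1.6262	-1.8345	-1.1589	0.0454	1.4726	-0.3253	0.6318	-0.6443	-0.2925	-1.0248	-0.5472	1.2379	0.0992
F	1.1301	0.4745	0.9405	-0.5120	0.5328	2.4941	-0.3157	0.9792	-1.7048	0.4939	-1.0323	-0.4420	0.3817	-1.8243	-0.0488	0.0441	0.6263	-0.2819	0.1693
G	0.0309	-1.5695	-2.0555	0.9368	0.3447	0.8205	-0.0316	-0.7759	0.5165	1.0272	0.4535	1.4545	-0.4583	-1.1375	1.2726	0.2232	-0.5560	0.8614	-1.5902
H	-0.9308	0.0000	0.6068	-1.2297	-0.8029	-1.1456	0.9078	-0.4416	-2.4984	0.4270	-0.9571	0.0569	-1.4458	1.5426	-0.2168	0.8273	-0.8832	0.3323	-0.3265
I	1.7140	0.2920	-0.1903	0.4358	-0.0720	0.5974	-0.0026	1.5921	0.1249	-2.0912	-0.4892	-1.9297	-0.8926	-0.7223	0.1846	-0.6675	0.2215	-0.0659	-1.8218
K	-1.1713	0.5840	0.3086	0.3816	1.8345	-0.4976	2.1545	-0.8037	-0.3200	-0.1931	-0.0991	0.3182	0.0438	-0.2066	0.5122	-0.2895	-0.3519	-1.7038	-0.5594
L	1.4735	0.7665	-0.1903	2.1057	-0.7985	-0.2497	-0.0258	0.7564	-0.1704	2.4174	-0.1054	-0.3588	-0.8534	1.0072	0.7702	-0.4611	0.7461	-0.3352	-0.2429
M	0.8209	1.6425	0.4090	-1.1620	0.9517	0.1987	-0.1650	0.0599	2.4917	1.4071	-1.3881	-0.0199	-0.3685	0.3776	-1.2761	-0.6749	-1.0026	-0.0707	-0.1890
N	-1.0339	-1.2045	-0.1591	-0.4218	-1.1151	0.8363	-0.3563	-0.3858	-0.1923	-0.3722	-0.6532	0.1104	2.2011	1.5780	-0.0419	-2.4276	0.1330	-0.9123	-0.6552
P	-0.3813	-1.5695	-0.7235	-0.1329	-1.2972	0.5533	0.1598	-1.3330	0.7202	0.1636	-1.0098	-1.0054	-1.2904	-1.2017	-0.1217	-0.6353	1.6493	0.3775	1.9624
Q	-1.0339	0.4015	0.3073	-0.4805	0.1272	0.4665	-0.2172	0.1992	0.8198	-1.4170	0.6650	-0.0884	-1.1667	1.1830	2.4973	-0.4646	-1.2174	0.6215	1.2817
R	-1.3774	-0.0730	1.2400	0.2417	-0.3064	-1.1432	2.7460	-0.2744	0.6867	-0.2212	1.7215	-0.6020	0.9158	0.2747	-0.7550	0.3176	1.1787	1.0137	-0.0854
S	-0.1065	-0.8395	-1.0573	0.7066	0.7775	0.4784	-0.1998	-0.7759	-0.0830	-0.8669	-1.1934	0.1293	0.1824	-0.2421	-1.3144	0.2436	-1.0156	1.7916	-0.3632
T	-0.0721	-0.6205	-0.5912	0.1559	1.2831	-1.8109	-0.2462	0.4499	-0.1402	0.1181	-1.1914	0.1592	2.1271	0.1684	1.7975	1.0734	0.8338	0.5779	1.2882
V	1.6109	0.2190	-0.6567	0.8465	0.9727	-0.3162	-0.0374	1.8707	-0.3535	-0.5662	0.5464	1.4545	-0.3829	1.0792	-1.8228	-0.1000	0.2982	0.6429	1.4346
W	-0.1408	0.2920	2.2380	-1.7668	-1.6778	-0.4736	-0.0780	0.9514	0.5796	-0.4489	-0.0499	2.3006	0.1086	-0.7271	0.2676	0.5121	0.9956	0.4779	-1.1700
Y	-0.2782	-1.1315	1.4724	-0.9363	-0.7041	0.1398	-0.2114	1.2299	0.3595	1.1808	1.1833	-1.8931	1.1149	-0.2930	-0.1902	1.3584	-1.7058	0.0599	0.0672
"""


def default_scales() -> ScaleSet:
    """The packaged 19-scale set (synthetic stand-in, see module docstring)."""
    return read_scales(_io.StringIO(_DEFAULT_SCALES_TSV))
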