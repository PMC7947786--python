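# Published 32-member combinatorial Dop mutant library: which of the five
# supporting-mutation segments carry the PafA residue set in each library member.
# Member 1 is the fully PafA-like variant (all segments on); member 31 is the
# alpha-loop-only backbone (all segments off). Segment unit names:
# 1 = S27A,V31F; 2 = I85F; 3 = V94L + V insertion + H96G + A97S ("VHA to LVGS");
# 4 = S102A,A103T,P104A; 5 = S450D.
member	segment1	segment2	segment3	segment4	segment5
1	1	1	1	1	1
2	0	0	0	1	0
3	0	0	1	1	0
4	1	0	0	1	0
5	0	1	0	1	0
6	0	0	0	1	1
7	1	0	1	0	0
8	0	1	1	0	0
9	1	1	0	0	0
10	1	0	0	0	1
11	0	1	0	0	1
12	1	0	1	1	0
13	0	1	1	1	0
14	1	1	0	1	0
15	1	1	1	0	0
16	0	0	1	1	1
17	1	0	0	1	1
18	1	0	1	0	1
19	0	1	0	1	1
20	1	1	0	0	1
21	1	1	0	1	1
22	0	1	1	1	1
23	1	0	1	1	1
24	0	0	1	0	0
25	1	0	0	0	0
26	0	0	0	0	1
27	0	0	1	0	1
28	0	1	1	0	1
29	1	1	1	0	1
30	1	1	1	1	0
31	0	0	0	0	0
32	0	1	0	0	0
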