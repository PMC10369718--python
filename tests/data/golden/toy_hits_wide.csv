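query_index,query_name,chrom,query_start,query_end,query_strand,tfbs_present,tfbs_count,tfbs_names,cgi_present,cgi_count,cgi_names,promoters_present,promoters_count,promoters_names
0,g0,chr1,1000,2000,+,True,3,t0;t1;t2,True,1,c0,True,1,p0
1,g1,chr1,3000,3500,+,True,1,t4,False,0,,True,1,p1
2,g2,chr1,5000,7000,-,True,2,t5;t6,True,1,c1,True,1,p2
3,g3,chr1,9000,9100,+,True,1,t7,False,0,,True,1,p3
4,g4,chr1,12000,15000,+,True,1,t8,False,0,,True,1,p4
5,g5,chr2,1000,2000,+,True,1,t9,True,1,c3,False,0,
6,g6,chr2,4000,4200,-,False,0,,False,0,,False,0,
7,g7,chr2,6000,9000,+,True,1,t10,True,1,c4,True,1,p5
8,g8,chr2,10000,10050,+,False,0,,False,0,,True,1,p6
9,g9,chr3,500,1500,+,False,0,,False,0,,False,0,
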