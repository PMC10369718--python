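query_dataset,query_index,query_name,chrom,query_start,query_end,query_strand,subject_dataset,subject_index,subject_name,subject_start,subject_end,subject_strand,ov_start,ov_end,ov_width,frac_query,frac_subject
genes,0,g0,chr1,1000,2000,+,cgi,0,c0,900,1200,*,1000,1200,201,0.200799,0.667774
genes,0,g0,chr1,1000,2000,+,promoters,0,p0,800,1000,+,1000,1000,1,0.000999001,0.00497512
genes,0,g0,chr1,1000,2000,+,tfbs,0,t0,1100,1110,*,1100,1110,11,0.010989,1
genes,0,g0,chr1,1000,2000,+,tfbs,1,t1,1500,1520,*,1500,1520,21,0.020979,1
genes,0,g0,chr1,1000,2000,+,tfbs,2,t2,1990,2010,*,1990,2000,11,0.010989,0.52381
genes,1,g1,chr1,3000,3500,+,promoters,1,p1,2900,3000,+,3000,3000,1,0.00199601,0.00990099
genes,1,g1,chr1,3000,3500,+,tfbs,4,t4,3400,3600,*,3400,3500,101,0.201597,0.502488
genes,2,g2,chr1,5000,7000,-,cgi,1,c1,4950,5100,*,5000,5100,101,0.0504748,0.668874
genes,2,g2,chr1,5000,7000,-,promoters,2,p2,6900,7100,-,6900,7000,101,0.0504748,0.502488
genes,2,g2,chr1,5000,7000,-,tfbs,5,t5,5000,5050,*,5000,5050,51,0.0254873,1
genes,2,g2,chr1,5000,7000,-,tfbs,6,t6,6995,7005,*,6995,7000,6,0.0029985,0.545455
genes,3,g3,chr1,9000,9100,+,promoters,3,p3,8900,9000,+,9000,9000,1,0.00990099,0.00990099
genes,3,g3,chr1,9000,9100,+,tfbs,7,t7,9000,9100,*,9000,9100,101,1,1
genes,4,g4,chr1,12000,15000,+,promoters,4,p4,11800,12100,+,12000,12100,101,0.0336554,0.335548
genes,4,g4,chr1,12000,15000,+,tfbs,8,t8,13000,13100,*,13000,13100,101,0.0336554,1
genes,5,g5,chr2,1000,2000,+,cgi,3,c3,950,1050,*,1000,1050,51,0.0509491,0.50495
genes,5,g5,chr2,1000,2000,+,tfbs,9,t9,1000,1000,*,1000,1000,1,0.000999001,1
genes,7,g7,chr2,6000,9000,+,cgi,4,c4,6000,9000,-,6000,9000,3001,1,1
genes,7,g7,chr2,6000,9000,+,promoters,5,p5,5800,6050,+,6000,6050,51,0.0169943,0.203187
genes,7,g7,chr2,6000,9000,+,tfbs,10,t10,8000,8100,*,8000,8100,101,0.0336554,1
genes,8,g8,chr2,10000,10050,+,promoters,6,p6,9950,10010,+,10000,10010,11,0.215686,0.180328
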