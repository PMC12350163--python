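{
 "fixture": {
  "clusters.bed": "8136050dd4502aa271086b6e1ae8c4b58332885bb9b8e33cc2e67730921673f0",
  "compartments.bed": "eb90c377c9e3ec147bb1e0c52c3599600ea0208ce700d41ec3be9cb7c3b583f5",
  "config.yaml": "94b9386c2bfe39d72265071810c019fa1ece1423a6929222e71de73e7c4c2964",
  "genome.chrom.sizes": "70fccbbbd48ae4422b351f6166ac4720616c04d0e2b5c618d454bc919305bac7",
  "genome.fa": "54c3e93f38ceded04fddbebde363bc09d4b82e727c7dee36c8193efb965e4c97",
  "marks/H3K27me3_EzKD_rep0.bed": "60e26e48507b53f1e428e15050812cc645891f50bf540db076762ac43fdfc96b",
  "marks/H3K27me3_EzKD_rep1.bed": "ab665e1e1612f9ff426f54d0897f154916e89afef6cbce0764208f62637362ae",
  "marks/H3K27me3_control_rep0.bed": "6e98702fdc623ac103adfabdcf40636868f43e69b59bffbdcdce7e18908a93e6",
  "marks/H3K27me3_control_rep1.bed": "c51cf43f191f97e6c61a4f4b70e9f7817b8543b06250774efb3210de1ac59e24",
  "marks/H3K9me3_control_rep0.bed": "3c0e51068dc997075809804dc6a25e9a41884ced12c91116dc94d2f93afc96de",
  "marks/H3K9me3_control_rep1.bed": "ad4f33796a7e87ade84528401ad653e8c006553970ffe9bb5cf3090e7964cb3a",
  "marks/IgG_control_rep0.bed": "3506511e342db7e163864dd9fa6adde44d9803c381d95984c80fc0ce3c611b7a",
  "marks/Rhi_EzKD_rep0.bed": "5a9335b254d631f9754469f1aeb4348bbdfc75316eb4c82d9e1b891ab20cd4c3",
  "marks/Rhi_EzKD_rep1.bed": "e81838e4fce9a4da08793ffc2ad340c0faa86477cd6e61b716299f7947cf6b64",
  "marks/Rhi_control_rep0.bed": "05a7bf3917712a2b622a6ad9b8239f7c9f0ba1c47b27cf0fb791b7f5d007142b",
  "marks/Rhi_control_rep1.bed": "d8188ad5d90ba79fba28c84a75ac6cf0557ab0262f439cc103cd78585be6b2e6",
  "peaks/H3K27me3_control_rep0.bed": "558235f1b5b2da434437a9d109fb94916b601467abcba09524a5a5228241bf11",
  "peaks/H3K27me3_control_rep1.bed": "558235f1b5b2da434437a9d109fb94916b601467abcba09524a5a5228241bf11",
  "peaks/H3K9me3_control_rep0.bed": "ab4e50259466014bb7ac440f0ce6b8284ea97ada12111744f938e3213f917327",
  "peaks/H3K9me3_control_rep1.bed": "ab4e50259466014bb7ac440f0ce6b8284ea97ada12111744f938e3213f917327",
  "peaks/Rhi_control_rep0.bed": "8d23c0ac33a53061eb7a7a5897ba692298ac993feeb0bd68267a26258aca61b2",
  "peaks/Rhi_control_rep1.bed": "8d23c0ac33a53061eb7a7a5897ba692298ac993feeb0bd68267a26258aca61b2",
  "peaks/Rhi_kipfKD_rep0.bed": "06979d8216380d3993457afeee35b2c03d579ad0346fd583d86b73df4365e92f",
  "peaks/Rhi_kipfKD_rep1.bed": "06979d8216380d3993457afeee35b2c03d579ad0346fd583d86b73df4365e92f",
  "peaks/Rhi_rhiKD_rep0.bed": "a803f1aa6203d0b4cebc15c9ead9b34d7e7c105740abf55c5fea1b6b32ef3d85",
  "peaks/Rhi_rhiKD_rep1.bed": "a803f1aa6203d0b4cebc15c9ead9b34d7e7c105740abf55c5fea1b6b32ef3d85",
  "pirna/EzKD_rep0.bed": "331a6fa86dbfdb4f5d6608c5aeea77a9b49c45c1d8cf9330f069c1fd517354bc",
  "pirna/EzKD_rep1.bed": "0e45f91d6bf935b12d05fddc30180ed078e2baee14002ff66448dbf1944363f4",
  "pirna/control_rep0.bed": "807049427efc3d9b8d6dacbec7b5e14097d607f65fe127757435f2b2cccf7d83",
  "pirna/control_rep1.bed": "f6407b3e12f36397301c5f4c24499570d38cd9a625adbd38274cf15c3714695e",
  "pirna/doubleKD_rep0.bed": "eceb9e2964bab7fd80a6c061110bf5fbaf33596aecc49762b8cb7074212ba5eb",
  "pirna/doubleKD_rep1.bed": "94130ba245bc1f0945b79935ebe3c0254c652183eca9745f3b6d73750739381f",
  "pirna/kipfKD_rep0.bed": "524396c2994240dae89bc1e8d5cc5138059e6964a0464a83028171f0414c5c66",
  "pirna/kipfKD_rep1.bed": "a6e9f589bd4161bda22ef795d654be8e5772acfe4311fb69660c23f98037a28b",
  "pirna/rhiKD_rep0.bed": "8e75425b71f73cf6957f1a3984a3d2217ba6b95c1229aaa7f240920a4e10a6f7",
  "pirna/rhiKD_rep1.bed": "612829bc0f3bfab3966cb0178e42f4a8bfc9c6d80f1631dc14d96fe0d4fd2414",
  "truth.tsv": "99bf4a8eb1b97e5dc18281514bf4391c9641df465b106d9068c4d891a4baac46"
 },
 "results": {
  "auc.tsv": "7e85cb90e03bae82079dcbc30170d14b9c2fad64380efe6eab7b1cf16849b4ab",
  "bins.tsv": "da6bc30460807ad81dc035730032113e70b8729633cd5776024f8254306089b6",
  "delta_groups.tsv": "3969fda742ed6ba2ae7e7111beb3deccbf83758ce67a2372da412b6cd6efdaa9",
  "dependency.tsv": "cbed6696f42c83abf6caca38cf0f037b45649a70ff4e0c9f5d65462d5b8b594a",
  "filter_report.tsv": "4d41b781b2575046a5e7a592ceec05a8b9905ab481fec93d3b1226e003384e5c",
  "level_groups.tsv": "26a19593c679932d2d8a59c9f49e7f683d09eb0c8a9b85730b36777cc671fdea",
  "mark_enrichment.tsv": "7e085e8d601b8246b7b57bc30e967dfb2dbb94ba993c69b8320024b99195ac93",
  "or_table.tsv": "1f0fb97b91c236fb0c1eb630df4631ebdbd7c7ab860d9320ccf1a7fbb740db8c",
  "peak_dependency.tsv": "196d6f0d237fb3c3809141277cc23de8b552b6d8c0c5a1faf0a493026c986be5",
  "pirna_cpm_EzKD.tsv": "b5ff521ddb18f7daf2ec775dd0df52bb133bd769e9f4f248157dbad5385c0339",
  "pirna_cpm_control.tsv": "ede7f5aa9235c5909908b2a08038cb76653ccdc73d83972c06d7969c67aa2581",
  "pirna_cpm_doubleKD.tsv": "7c634dd311462e9191ae36fd23ee9769b9e3b42574b74d1deffda389fb7f8e54",
  "pirna_cpm_kipfKD.tsv": "d53293ffca0d0b38c8712b59219cb8988d96e2a9c08d6d3e119b5d311505e910",
  "pirna_cpm_rhiKD.tsv": "1388ce3b81498e4f8f1d19240da71a1e85788726426b0550d93c8ee6d1839d1a",
  "report.json": "689e9dc4604e87cc9e1d11cb2806d231021d076d92b7feb140f74904815cc4db",
  "rhi_dependency.tsv": "826e650baf86ed30c4258fff43fe9ef6d910f681fd207b107feb852d0e3a8648",
  "venn.tsv": "5a59522a35160cc9effcea5f06c4fc3dbe217d080fcf881e93eecb641730a49b"
 }
}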