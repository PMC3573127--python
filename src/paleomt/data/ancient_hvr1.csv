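sample_id,site,motif,hg_hvr,hg_coding
UZOO-43,aUz,129c-189C-362C,U2e,U
UZOO-46,aUz,129c-189C-362C,U2e,U
UZOO-16,aUz,093C-356C,U4,U
UZOO-40,aUz,093C-356C,U4,U
UZOO-70,aUz,192T-256T-270T-318G,U5a,U
UZOO-77,aUz,235G-311C-362C,H,H
UZOO-7,aUz,189C-223T-298C-325C-327T,C1,C
UZOO-8,aUz,189C-223T-298C-325C-327T,C1,C
UZOO-74,aUz,189C-223T-298C-325C-327T,C1,C
Po4,aPo,356C,U4,U
Po2,aPo,093C-356C,U4,U
BOO49-3,aBOO,093C-129A-134T-311C-356C,U4a1,U
BOO57-1,aBOO,093C-129A-134T-311C-356C-(390R),U4a1,U
BOO49-1,aBOO,192T-256T-270T,U5a,U
BOO72-11,aBOO,192T-256T-270T,U5a,U
BOO72-9,aBOO,192T-256T-270T-399G,U5a1,U
BOO72-10,aBOO,192T-256T-270T-399G,U5a1,U
BOO72-14,aBOO,192T-256T-270T-399G,U5a1,U
BOO72-8,aBOO,192T-256T-270T-399G,U5a1,U
BOO72-4,aBOO,093C-126C-294T,T*,T
BOO49-2,aBOO,223T-298C-327T,C*,C
BOO49-4,aBOO,223T-298C-327T,C*,C
BOO57-3,aBOO,223T-298C-327T,C*,C
BOO72-2,aBOO,223T-298C-327T,C*,C
BOO72-7,aBOO,223T-298C-327T,C*,C
BOO72-12,aBOO,223T-298C-327T,C*,C
BOO72-5,aBOO,148T-223T-288C-298C-311C-327T,C5,C
BOO72-6,aBOO,148T-223T-288C-298C-311C-327T,C5,C
BOO49-6,aBOO,223T-362C,D*,D
BOO72-13,aBOO,223T-362C,D*,D
BOO72-15,aBOO,223T-362C,D*,D
BOO49-5,aBOO,129A-185T-223T-224C-260T-298C,Z1a,M
BOO72-3,aBOO,129A-185T-223T-224C-260T-298C,Z1a,M
BOO72-1,aBOO,129A-155G-185T-223T-224C-260T-298C,Z1a,M
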