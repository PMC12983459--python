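>PSMB8_A_ref1|PSMB8;A
MDAPVIKLGEQYIKVDGANMTTTLLSERDFAEIQPYIVQSSNHTYPVKGTAGNYMDVAQP
IIMAAEGAQEAMGYLSRLHVTHVDFSESQSLPDQRQLCTPFKLTYPMRPQWRDENPEASF
GSEQVNSAKPLEALILRKRVLCFEQISINEFSGEVMLDFEVVGYQNMGSESVIGKGAQRR
RYADGRGAISISEPTVTGFMLGTVLYWCKDYETEHQRDGGGHRG
>PSMB8_A_ref2|PSMB8;A
MDAPVIKLGEQYIKVDGANMTTTLLSEYDFAEIQPYIVQSSNHTYPVKGTAGNYMDVAQP
IIMAAEGAQEAMGYLSYLHVTHVDFSESQSLPDQRQLCTPFKLTYPMRPQWRDENPEASF
MSEQVNSAKPLEALILRKRVLCFEQISINEFSMEVMLDFEVVGYQNMGSESVIGKGAQRR
RYADGRGAISIAEPTVTGFMLGTVLYWCKDYETEHQRDGGGHRG
>PSMB8_F_ref1|PSMB8;F
MDAPVIKLGEQYIKVDGANMTTTLLSERDFAEMQPYIVQSTNHGYPVKGTFYNYMDVAQP
IIMAAEGAQEAMGYLSRLNVTHVDFSESQSLPDIIQLCTPFKLTYPMRPQWRQENPEATF
GSEQVNSAKPLEALILRKRHPCFEQISDNEFSGEVMLDFEVCGYQNLGSPSVIGDAAQRD
RYARFRGWIMGSDPTVTGFMQGTVLYWSQDYATDHQRDGGGHRG
>PSMB8_F_ref2|PSMB8;F
MDAPVIKLGEQYIKVDGANMTTTLLSERIFAEMQPYIVQSTNHGYPVKGTFYNYMDVAQP
IIMAAEGAQEAMGYLSRRNVTHVDFSESQSLPDIIQLCTPFKLTYPMRPQWRQENPEATF
GAEQVNSAKPLEALILRKRHPCFEQISDNEFSGKVMLDFEVCGYQNLGSPSVIGDAAQRD
RYARFRGWIMGSIPTVTGFMQGTVLYWSQDYATDHQRDGGGHRG
>PSMB5_Homo_synthetic|PSMB5
MDYGNIKLGVESIKDQWANMTTTQLEGRYFAEVCPYSVDVQPDGYPVKGSAYTQMDVAQP
RIMWLEQRQEQAGYLGQLHVILVVPWDSQSLPDIVQVYTPIWCTKPVESQWRQENPAGSC
GSEQGESYKLLKDLILIKRHLCFEQIFDNDISKEDMLVFCVSLYNRLCSETVHGDGATRD
RYADFPGAWMCSDPTQLWFMLGTVLYWSKDYATSHQRDGGAHVG
>PSMB5_Danio_synthetic|PSMB5
MDYGNIKLGVESIKDQWANMTTTQLEGRYNAEVCPYSVDVQPDGYPVKGSAYTQMDVAQP
RIMWLEQRQMQAGYLGQLHVILVVPWDSQSLPDIVQVYTPIWCTKPVESAWRQENPAGSC
GSEQGESYKLLKDLILIKRHLCFEQIFDNLISKEDMLVFCVSLYNRLCSETVHGDGATRD
RYADFPGAWVCSDPTQLWFMLGTVLYWSKDYATSHQRDGGAHVG
>PSMB5_Petromyzon_synthetic|PSMB5
MDYGNIKLGVESIKDQWANMTTTQLEGRYFAEVCYYSVDVQPDGYPVKGSAYTQMDVAQP
RIMWLEQRQEQAGYTGQLHVILVVPWDSQSLPDIVQVYTPIWCTKPVESQWRQEWPAGSC
GSEQGESYKLLKDLILIKRHLCFEQIFDNDISKELMLVFCVSLYNRLCSETVHGDGATRD
RYADFPGAWMCSDPEQLWFMLGTVLYWSKDYATSHQRDGGAHVG
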